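"""Somatic cell score and the record-retention filter.

SCC (somatic cell count, cells/mL) is transformed to the somatic cell score
SCS = log2(SCC / 100,000) + 3, the standard log score under which a doubling
of SCC adds exactly one point and SCC = 100,000 maps to 3. Records are kept
only when raw SCC lies inside a configured window (default [1e3, 5e5],
bounds inclusive); filtering precedes the transform.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import RunConfig, TestDayRecord


def compute_scs(scc) -> float | np.ndarray:
    """SCS = log2(SCC / 100,000) + 3. Accepts scalars or arrays; SCC must be > 0."""
    scc = np.asarray(scc, dtype=float)
    if np.any(~(scc > 0)):
        raise ValueError("SCC must be positive to compute SCS")
    out = np.log2(scc / 100_000.0) + 3.0
    return float(out) if out.ndim == 0 else out


def filter_records(
    records: Sequence[TestDayRecord], config: RunConfig | None = None
) -> tuple[list[TestDayRecord], list[tuple[TestDayRecord, str]]]:
    """Split records into (kept, dropped-with-reason) by the SCC window.

    Bounds are inclusive; every input record lands in exactly one output.
    """
    config = config or RunConfig()
    kept: list[TestDayRecord] = []
    dropped: list[tuple[TestDayRecord, str]] = []
    for r in records:
        if r.scc < config.scc_lower:
            dropped.append((r, f"SCC {r.scc:g} below lower bound {config.scc_lower:g}"))
        elif r.scc > config.scc_upper:
            dropped.append((r, f"SCC {r.scc:g} above upper bound {config.scc_upper:g}"))
        else:
            kept.append(r)
    return kept, dropped
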