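"""Probe-level quality filtering.

Probes are removed when they fail background detection in any sample
(detection p > 0.01), when they cross-hybridise to multiple genomic
locations, or when they overlap common SNPs.  Sex-chromosome probes are
retained by default — appropriate for a single-sex donor cohort — but can
be dropped with ``retain_sex=False``.  A probe may fail several rules; it
is listed under every applicable reason but removed (and counted in the
retention arithmetic) only once.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnalysisConfig, BetaMatrix, ProbeAnnotation
from .exceptions import ArgumentError, DataError

__all__ = ["FilterReport", "filter_probes", "summarize_filtering", "parse_filter_summary"]

_REASONS = ("detection", "cross_reactive", "snp", "sex")


@dataclass
class FilterReport:
    """Audit trail of one filtering pass."""

    n_input: int
    removed_ids_by_reason: dict[str, list[str]]
    retained_ids: list[str]

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def n_removed_for(self, reason: str) -> int:
        if reason not in _REASONS:
            raise ArgumentError(f"unknown removal reason {reason!r}")
        return len(self.removed_ids_by_reason.get(reason, []))

    @property
    def n_removed_detection(self) -> int:
        return self.n_removed_for("detection")

    @property
    def n_removed_cross_reactive(self) -> int:
        return self.n_removed_for("cross_reactive")

    @property
    def n_removed_snp(self) -> int:
        return self.n_removed_for("snp")

    @property
    def n_removed_sex(self) -> int:
        return self.n_removed_for("sex")


def filter_probes(
    b: BetaMatrix,
    ann: ProbeAnnotation,
    detp: pd.DataFrame | None,
    cfg: AnalysisConfig,
    retain_sex: bool = True,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the probe inclusion rules and return the filtered matrix.

    Removal rules (union): detection p strictly greater than
    ``cfg.detection_p_max`` in ANY sample; ``cross_reactive`` flag;
    ``snp_flag``; chromosome X/Y unless ``retain_sex``.  Output probe
    order is the input order restricted to survivors.
    """
    ann.check_covers(b.probe_ids)
    probe_index = pd.Index(b.probe_ids)
    table = ann.table.loc[probe_index]

    removed: dict[str, list[str]] = {r: [] for r in _REASONS}
    if detp is not None:
        missing = set(b.probe_ids) - set(detp.index)
        if missing:
            raise DataError(
                f"detection-p matrix lacks probe(s): {sorted(missing)[:5]}"
            )
        missing_s = set(b.sample_ids) - set(detp.columns)
        if missing_s:
            raise DataError(
                f"detection-p matrix lacks sample(s): {sorted(missing_s)[:5]}"
            )
        dvals = detp.loc[probe_index, b.sample_ids].to_numpy(dtype=float)
        fail = np.nanmax(dvals, axis=1) > cfg.detection_p_max  # strict >
        removed["detection"] = list(probe_index[fail])
    removed["cross_reactive"] = list(probe_index[table["cross_reactive"].to_numpy()])
    removed["snp"] = list(probe_index[table["snp_flag"].to_numpy()])
    if not retain_sex:
        removed["sex"] = list(probe_index[table["chromosome"].isin(["X", "Y"]).to_numpy()])

    drop = set().union(*removed.values())
    retained = [p for p in b.probe_ids if p not in drop]
    report = FilterReport(
        n_input=len(b.probe_ids),
        removed_ids_by_reason=removed,
        retained_ids=retained,
    )
    return b.subset_probes(retained), report


def summarize_filtering(r: FilterReport) -> pd.DataFrame:
    """One row per removal reason plus input/removed/retained totals."""
    rows = [{"category": f"removed_{reason}", "count": r.n_removed_for(reason)}
            for reason in _REASONS]
    rows += [
        {"category": "n_input", "count": r.n_input},
        {"category": "n_removed_unique", "count": r.n_removed},
        {"category": "n_retained", "count": r.n_retained},
    ]
    return pd.DataFrame(rows)


def parse_filter_summary(text: str) -> pd.DataFrame:
    """Parse a summary table written with ``to_csv(sep='\\t')``."""
    return pd.read_csv(io.StringIO(text), sep="\t", comment="#")
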