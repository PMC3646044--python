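"""Variance-vs-abundance (Var-Ab) summaries.

Per-donor abundances are heavy-tailed, so variation is summarized on the
log10 scale: for each taxon, the mean and sample standard deviation of
log10 abundance over the "responding" donors (abundance >= a floor,
default 1e-4).  Zeros/below-floor values are treated as non-response and
excluded rather than imputed — a donor whose depth cannot resolve the
taxon carries no information about its abundance.

``proportion_variance`` gives the theoretical sampling variance of an
observed proportion p at depth n under simple random sampling,
p(1-p)/(n-1); it explains why very low-abundance taxa show low variance
even absent any biology, which is why the Var-Ab view is used for
visual comparison rather than variance correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import CohortProfile, ValidationError

__all__ = ["VarAbRecord", "proportion_variance", "varab_table", "varab_frame"]


@dataclass(frozen=True)
class VarAbRecord:
    taxon: str
    mean_log_abundance: float  # mean of log10 abundances over responders
    sd_log_abundance: float | None  # sample sd (n-1); None when n_responding == 1
    ubiquity: float  # fraction of donors responding (>= floor)
    n_responding: int


def proportion_variance(p: float, n: int) -> float:
    """Sampling variance of a sample proportion: p(1-p)/(n-1)."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p={p} outside [0, 1]")
    if n < 2:
        raise ValidationError(f"n={n} must be >= 2")
    return p * (1.0 - p) / (n - 1)


def varab_table(profile: CohortProfile, floor: float = 1e-4) -> list[VarAbRecord]:
    """Per-taxon log10-abundance mean/sd over responding donors.

    Donors below ``floor`` are non-responses and excluded; taxa with no
    responders are omitted; a single responder yields sd ``None`` (the
    glyph can still be plotted, but spread is undefined).
    """
    if floor <= 0:
        raise ValidationError(f"floor must be > 0, got {floor}")
    A = profile.values()
    out: list[VarAbRecord] = []
    for j, taxon in enumerate(profile.taxon_labels):
        vals = A[:, j]
        resp = vals >= floor
        k = int(resp.sum())
        if k == 0:
            continue
        logs = np.log10(vals[resp])
        sd = float(np.std(logs, ddof=1)) if k >= 2 else None
        out.append(
            VarAbRecord(
                taxon=taxon,
                mean_log_abundance=float(np.mean(logs)),
                sd_log_abundance=sd,
                ubiquity=k / profile.n_donors,
                n_responding=k,
            )
        )
    return out


def varab_frame(profile: CohortProfile, floor: float = 1e-4) -> pd.DataFrame:
    """DataFrame view of :func:`varab_table` (sd is NaN when undefined)."""
    recs = varab_table(profile, floor)
    return pd.DataFrame(
        {
            "taxon": [r.taxon for r in recs],
            "mean_log10_abundance": [r.mean_log_abundance for r in recs],
            "sd_log10_abundance": [np.nan if r.sd_log_abundance is None else r.sd_log_abundance for r in recs],
            "ubiquity": [r.ubiquity for r in recs],
            "n_responding": [r.n_responding for r in recs],
        }
    )
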