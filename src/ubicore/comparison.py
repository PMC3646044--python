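"""Two-cohort comparison: per-taxon KS distances, the abundance-weighted
KS (AWKS) statistic, bootstrap inference, BH correction, and U-U curves.

For one taxon, the KS distance between cohorts X and Y is the largest
absolute difference between their ubiquity curves at matching abundance
cutoffs:

    KS_t = max_a | Ubiq(X, t, a) - Ubiq(Y, t, a) |

Both curves are step functions that only change at observed abundances,
so the supremum is attained on {0} union the observed values and the
statistic is exact.  AWKS aggregates over the union taxa set T with
compositional weights

    AWKS = sum_{t in T} w_t * KS_t,   w_t = (meanAbund_X(t) + meanAbund_Y(t)) / 2

which sum to 1 by closure, so AWKS is in [0, 1] and bounded by max KS_t.

Significance is assessed against a bootstrap null: donors from both
cohorts are pooled (exchangeable under H0: same taxonomic profile), n_X
and n_Y pseudo-donors are drawn with replacement, each drawn donor's
reads are redrawn as a multinomial of its depth over its observed
proportions, and AWKS is recomputed; the one-tailed p-value is the
fraction of null draws >= the observed statistic.  The empirical null
is used directly — no normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import CohortProfile, TaxonCountTable, ValidationError, normalize

__all__ = [
    "UUCurve",
    "ComparisonResult",
    "ks_taxon",
    "awks",
    "awks_details",
    "awks_test",
    "bh_adjust",
    "uu_curve",
]

NULL_MODES = ("pooled", "within-first")


# ---------------------------------------------------------------------------
# Alignment helpers


def _union_matrices(x: CohortProfile, y: CohortProfile) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Abundance matrices of both cohorts over the sorted union taxa set
    (absent taxa padded with zeros)."""
    taxa = sorted(set(x.taxon_labels) | set(y.taxon_labels))
    ax = x.to_frame().reindex(columns=taxa, fill_value=0.0).to_numpy()
    ay = y.to_frame().reindex(columns=taxa, fill_value=0.0).to_numpy()
    return taxa, ax, ay


def _taxon_values(profile: CohortProfile, taxon: str) -> np.ndarray:
    if taxon in profile:
        return profile.abundance_vector(taxon)
    return np.zeros(profile.n_donors)


def _survival(values: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Ubiq evaluated at each cutoff in ``at``: fraction strictly above."""
    srt = np.sort(values)
    return (len(srt) - np.searchsorted(srt, at, side="right")) / len(srt)


def _ks_breakpoints(vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    return np.unique(np.concatenate([[0.0], vx, vy]))


def _ks_all(ax: np.ndarray, ay: np.ndarray) -> np.ndarray:
    """Per-column two-sample KS between the survival curves of ``ax`` and
    ``ay`` (donors x taxa), vectorized across taxa.

    Pools the two samples per column, sorts, and walks the signed step
    +1/n_x for X donors and -1/n_y for Y donors; the running sum at the
    end of each tie group is S_Y - S_X evaluated just past that value,
    whose maximum absolute value over all observed values (a=0 included
    implicitly: the difference there is 0 unless 0 is observed) is KS_t.
    """
    nx, _ = ax.shape
    ny = ay.shape[0]
    z = np.concatenate([ax, ay], axis=0)
    w = np.concatenate([np.full(nx, 1.0 / nx), np.full(ny, -1.0 / ny)])
    order = np.argsort(z, axis=0, kind="stable")
    zs = np.take_along_axis(z, order, axis=0)
    ws = w[order]
    cum = np.cumsum(ws, axis=0)
    group_end = np.ones_like(cum, dtype=bool)
    group_end[:-1] = zs[1:] != zs[:-1]
    return np.where(group_end, np.abs(cum), 0.0).max(axis=0)


# ---------------------------------------------------------------------------
# Public statistics


def ks_taxon(x: CohortProfile, y: CohortProfile, taxon: str) -> float:
    """Max absolute ubiquity difference for one taxon (exact; a taxon
    absent from a cohort contributes an all-zero abundance vector)."""
    vx = _taxon_values(x, taxon)
    vy = _taxon_values(y, taxon)
    br = _ks_breakpoints(vx, vy)
    return float(np.max(np.abs(_survival(vx, br) - _survival(vy, br))))


def awks_details(x: CohortProfile, y: CohortProfile) -> pd.DataFrame:
    """Per-taxon KS statistics and compositional weights over the union."""
    if x.n_donors == 0 or y.n_donors == 0:
        raise ValidationError("both cohorts must be non-empty")
    taxa, ax, ay = _union_matrices(x, y)
    ks = _ks_all(ax, ay)
    weights = (ax.mean(axis=0) + ay.mean(axis=0)) / 2.0
    return pd.DataFrame({"taxon": taxa, "ks": ks, "weight": weights})


def awks(x: CohortProfile, y: CohortProfile) -> float:
    """Abundance-weighted average of per-taxon KS statistics."""
    d = awks_details(x, y)
    return float(np.dot(d["weight"], d["ks"]))


@dataclass(frozen=True)
class ComparisonResult:
    taxa: tuple[str, ...]
    ks: np.ndarray  # per-taxon KS over the union
    weights: np.ndarray  # compositional weights, sum to 1
    awks: float
    null: np.ndarray  # B bootstrap null draws of AWKS
    p_count: int  # number of null draws >= observed
    p_value: float  # p_count / B
    b: int
    seed: int | None
    n_x: int
    n_y: int
    null_mode: str
    add_one: bool = False

    @property
    def p_label(self) -> str:
        """Display form: '< 1/B' when no null draw reaches the observed value."""
        if self.p_count == 0 and not self.add_one:
            return f"<{1.0 / self.b:g}"
        return f"{self.p_value:g}"


def awks_test(
    table_x: TaxonCountTable,
    table_y: TaxonCountTable,
    b: int = 1000,
    seed: int | None = None,
    null_mode: str = "pooled",
    add_one: bool = False,
) -> ComparisonResult:
    """Observed AWKS plus a bootstrap null distribution and empirical p-value.

    ``null_mode='pooled'`` (default) draws both pseudo-cohorts from the
    pooled donors of X and Y; ``'within-first'`` draws both from cohort X
    only, quantifying the statistic's variance within a single cohort.
    ``add_one`` switches the p-value to (count+1)/(B+1).
    """
    if b < 2:
        raise ValidationError(f"need at least 2 bootstrap replicates, got {b}")
    if null_mode not in NULL_MODES:
        raise ValueError(f"null_mode must be one of {NULL_MODES}, got {null_mode!r}")
    px = normalize(table_x)
    py = normalize(table_y)
    taxa, ax, ay = _union_matrices(px, py)
    ks = _ks_all(ax, ay)
    weights = (ax.mean(axis=0) + ay.mean(axis=0)) / 2.0
    observed = float(np.dot(weights, ks))

    nx, ny = px.n_donors, py.n_donors
    if null_mode == "pooled":
        pool_props = np.concatenate([ax, ay], axis=0)
        pool_depths = np.concatenate([table_x.depths.to_numpy(), table_y.depths.to_numpy()])
    else:
        pool_props = ax
        pool_depths = table_x.depths.to_numpy()

    rng = np.random.default_rng(seed)
    npool = pool_props.shape[0]
    null = np.empty(b)
    for rep in range(b):
        idx = rng.integers(0, npool, size=nx + ny)
        redrawn = rng.multinomial(pool_depths[idx], pool_props[idx])
        ab = redrawn / redrawn.sum(axis=1, keepdims=True)
        bx, by = ab[:nx], ab[nx:]
        w = (bx.mean(axis=0) + by.mean(axis=0)) / 2.0
        null[rep] = np.dot(w, _ks_all(bx, by))

    count = int(np.sum(null >= observed))
    p = (count + 1) / (b + 1) if add_one else count / b
    return ComparisonResult(
        taxa=tuple(taxa),
        ks=ks,
        weights=weights,
        awks=observed,
        null=null,
        p_count=count,
        p_value=float(p),
        b=b,
        seed=seed,
        n_x=nx,
        n_y=ny,
        null_mode=null_mode,
        add_one=add_one,
    )


# ---------------------------------------------------------------------------
# Multiple testing


def _resolve_p(p) -> float:
    """Accept floats or interval strings like '<0.001' (resolved to the
    midpoint of (0, bound), which cannot change step-up decisions)."""
    if isinstance(p, str):
        s = p.strip()
        if s.startswith("<"):
            bound = float(s[1:])
            return bound / 2.0
        return float(s)
    return float(p)


def bh_adjust(pvalues, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up decisions with per-rank thresholds.

    Returns a DataFrame in the input order with columns: ``p_value``
    (resolved), ``rank`` (ascending p), ``threshold`` (rank*alpha/m,
    unrounded), ``threshold_reported`` (rounded to 3 decimals, the
    convention used when printing), and ``reject``.  Decisions use the
    step-up rule on unrounded thresholds: reject every test whose rank is
    at most the largest i with p_(i) <= i*alpha/m.
    """
    if len(pvalues) == 0:
        raise ValidationError("empty p-value list")
    p = np.array([_resolve_p(v) for v in pvalues])
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    thresholds = ranks * alpha / m
    sorted_p = p[order]
    ok = sorted_p <= np.arange(1, m + 1) * alpha / m
    k = int(np.max(np.nonzero(ok)[0]) + 1) if ok.any() else 0
    reject = ranks <= k
    return pd.DataFrame(
        {
            "p_value": p,
            "rank": ranks,
            "threshold": thresholds,
            "threshold_reported": np.round(thresholds, 3),
            "reject": reject,
        }
    )


# ---------------------------------------------------------------------------
# U-U curves


@dataclass(frozen=True)
class UUCurve:
    """Parametric (Ubiq_X, Ubiq_Y) trace of one taxon over the merged
    breakpoint set; the argmax point marks the KS statistic's location."""

    taxon: str
    abundances: np.ndarray
    ubiquity_x: np.ndarray
    ubiquity_y: np.ndarray
    argmax_abundance: float
    argmax_pair: tuple[float, float]

    @property
    def ks(self) -> float:
        ux, uy = self.argmax_pair
        return abs(ux - uy)


def uu_curve(x: CohortProfile, y: CohortProfile, taxon: str) -> UUCurve:
    vx = _taxon_values(x, taxon)
    vy = _taxon_values(y, taxon)
    br = _ks_breakpoints(vx, vy)
    ux = _survival(vx, br)
    uy = _survival(vy, br)
    j = int(np.argmax(np.abs(ux - uy)))
    return UUCurve(
        taxon=taxon,
        abundances=br,
        ubiquity_x=ux,
        ubiquity_y=uy,
        argmax_abundance=float(br[j]),
        argmax_pair=(float(ux[j]), float(uy[j])),
    )
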