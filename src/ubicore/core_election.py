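"""Ubiquity curves, two-parameter core election, minor core, body regions.

The ubiquity of taxon t at abundance cutoff a in a cohort of n donors is

    Ubiq(t, a) = (1/n) * sum_i I(Abund(i, t) > a)

i.e. the survival function of the per-donor abundance distribution, with a
strict inequality.  A taxon is a core member under the two-parameter
cutoff (a*, u*) when Ubiq(t, a*) > u* — strict on both parameters, so
ties exclude.  The "minor core" inverts the abundance requirement: taxa
present (>= a detection floor, default 1e-4) in a majority of donors yet
never exceeding a low abundance ceiling (default 1%) in any donor.

Confidence intervals on core counts come from a joint bootstrap:
donors are resampled with replacement, and each drawn donor's reads are
redrawn as a multinomial of its depth over its observed proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .profiles import CohortProfile, TaxonCountTable, ValidationError, normalize

__all__ = [
    "CoreCutoff",
    "UbiquityCurve",
    "CoreReport",
    "MinorCoreRecord",
    "ubiquity",
    "ubiquity_curve",
    "elect_core",
    "elect_minor_core",
    "region_ubiquity_mean",
    "region_ubiquity_and",
    "elect_region_core",
    "bootstrap_core_counts",
]


@dataclass(frozen=True)
class CoreCutoff:
    """Two-parameter cutoff: abundance a* in (0,1), ubiquity u* in (0,1]."""

    abundance: float
    ubiquity: float

    def __post_init__(self) -> None:
        if not 0.0 < self.abundance < 1.0:
            raise ValidationError(f"abundance cutoff {self.abundance} not in (0, 1)")
        if not 0.0 < self.ubiquity <= 1.0:
            raise ValidationError(f"ubiquity cutoff {self.ubiquity} not in (0, 1]")

    def __str__(self) -> str:
        return f"{self.abundance:g}|{self.ubiquity:g}"


@dataclass(frozen=True)
class UbiquityCurve:
    """Exact step representation of Ubiq(t, a) as a function of a.

    ``breakpoints`` are the distinct observed abundances (sorted);
    ``ubiquities[j]`` is the fraction of donors strictly above
    ``breakpoints[j]``.  Between breakpoints the curve is constant
    (right-continuous step interpolation); at the largest observed
    abundance the ubiquity is 0.
    """

    taxon: str
    breakpoints: np.ndarray
    ubiquities: np.ndarray
    _sorted_values: np.ndarray = field(repr=False)

    def __call__(self, a) -> np.ndarray | float:
        """Evaluate Ubiq(t, a) exactly for scalar or array ``a``."""
        n = len(self._sorted_values)
        idx = np.searchsorted(self._sorted_values, a, side="right")
        out = (n - idx) / n
        return float(out) if np.isscalar(a) else out

    def mean_abundance(self) -> float:
        """Cohort-average abundance, recovered as the integral of the
        survival curve over [0, max]."""
        return float(np.mean(self._sorted_values))


def ubiquity(profile: CohortProfile, taxon: str, a: float) -> float:
    """Fraction of donors whose abundance of ``taxon`` strictly exceeds ``a``."""
    if a < 0:
        raise ValidationError(f"abundance cutoff {a} must be >= 0")
    vals = profile.abundance_vector(taxon)
    return float(np.mean(vals > a))


def ubiquity_curve(profile: CohortProfile, taxon: str) -> UbiquityCurve:
    vals = np.sort(profile.abundance_vector(taxon))
    br = np.unique(vals)
    n = len(vals)
    ub = (n - np.searchsorted(vals, br, side="right")) / n
    return UbiquityCurve(taxon=taxon, breakpoints=br, ubiquities=ub, _sorted_values=vals)


def elect_core(profile: CohortProfile, cutoff: CoreCutoff) -> set[str]:
    """Taxa with Ubiq(t, a*) > u*, strict on both parameters."""
    ub = (profile.values() > cutoff.abundance).mean(axis=0)
    labels = profile.taxon_labels
    return {labels[j] for j in np.nonzero(ub > cutoff.ubiquity)[0]}


@dataclass(frozen=True)
class MinorCoreRecord:
    taxon: str
    max_ubiquity: float  # fraction of donors at/above the detection floor
    max_abundance: float  # largest observed abundance across donors


def elect_minor_core(
    profile: CohortProfile,
    detection_floor: float = 1e-4,
    ubiquity_floor: float = 0.5,
    abundance_ceiling: float = 0.01,
    ceiling_tolerance: float = 0.0,
) -> list[MinorCoreRecord]:
    """Low-abundance majority taxa.

    A taxon qualifies when the fraction of donors with abundance >= the
    detection floor exceeds ``ubiquity_floor`` while the fraction of
    donors strictly above ``abundance_ceiling`` is at most
    ``ceiling_tolerance`` (0 by default: no donor may exceed the ceiling).
    Presence at the floor is inclusive (the curve "originates" at the
    floor); the ceiling check keeps the strict convention of Ubiq.
    """
    if not detection_floor < abundance_ceiling:
        raise ValidationError(
            f"detection_floor ({detection_floor}) must be < abundance_ceiling ({abundance_ceiling})"
        )
    A = profile.values()
    present = (A >= detection_floor).mean(axis=0)
    over = (A > abundance_ceiling).mean(axis=0)
    out = []
    for j, taxon in enumerate(profile.taxon_labels):
        if present[j] > ubiquity_floor and over[j] <= ceiling_tolerance:
            out.append(
                MinorCoreRecord(
                    taxon=taxon,
                    max_ubiquity=float(present[j]),
                    max_abundance=float(A[:, j].max()),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Body regions


def _habitat_ubiquity(profile: CohortProfile, taxon: str, a: float) -> float:
    """Ubiquity within one habitat; a taxon absent from the habitat has
    ubiquity 0 (it cannot be detected there)."""
    if taxon not in profile:
        return 0.0
    return ubiquity(profile, taxon, a)


def region_ubiquity_mean(profiles: list[CohortProfile], taxon: str, a: float) -> float:
    """Average of per-habitat ubiquities: the chance a habitat drawn from
    the region carries the taxon above ``a``."""
    if not profiles:
        raise ValidationError("need at least one habitat profile")
    return float(np.mean([_habitat_ubiquity(p, taxon, a) for p in profiles]))


def region_ubiquity_and(profiles: list[CohortProfile], taxon: str, a: float) -> float:
    """Product of per-habitat ubiquities: the chance the taxon is detected
    above ``a`` in every habitat of the region."""
    if not profiles:
        raise ValidationError("need at least one habitat profile")
    return float(np.prod([_habitat_ubiquity(p, taxon, a) for p in profiles]))


def elect_region_core(
    profiles: list[CohortProfile], cutoff: CoreCutoff, mode: str = "and"
) -> set[str]:
    """Region-level core over the union of the habitats' taxa."""
    if mode not in ("and", "mean"):
        raise ValueError(f"mode must be 'and' or 'mean', got {mode!r}")
    fn = region_ubiquity_and if mode == "and" else region_ubiquity_mean
    taxa = sorted({t for p in profiles for t in p.taxon_labels})
    return {t for t in taxa if fn(profiles, t, cutoff.abundance) > cutoff.ubiquity}


# ---------------------------------------------------------------------------
# Bootstrap CIs on core counts


@dataclass(frozen=True)
class CoreReport:
    cutoff: CoreCutoff
    taxa: frozenset[str]  # elected on the unperturbed table
    observed: int
    median: float
    lower: int
    upper: int
    b: int
    ci: float
    seed: int | None


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    """Nearest-rank percentile (no interpolation): the ceil(q*B)-th smallest."""
    b = len(sorted_vals)
    rank = max(1, math.ceil(q * b))
    return float(sorted_vals[rank - 1])


def bootstrap_core_counts(
    table: TaxonCountTable,
    cutoffs: list[CoreCutoff],
    b: int = 160,
    ci: float = 0.95,
    seed: int | None = None,
) -> list[CoreReport]:
    """Observed core counts with bootstrap median and CI bounds.

    Each replicate resamples donors with replacement and redraws every
    drawn donor's reads as a multinomial of its depth over its observed
    proportions, then re-elects the core.  The observed count is computed
    on the unperturbed table.  LB/UB are nearest-rank percentiles of the
    ``b`` replicate counts at (1-ci)/2 and 1-(1-ci)/2; the median is the
    standard sample median (mean of the two middle order statistics when
    ``b`` is even, hence half-integer medians are possible).
    """
    if b < 2:
        raise ValidationError(f"need at least 2 bootstrap iterations, got {b}")
    if table.n_donors == 0:
        raise ValidationError("empty table")
    profile = normalize(table)
    observed_sets = {c: frozenset(elect_core(profile, c)) for c in cutoffs}

    rng = np.random.default_rng(seed)
    props = profile.values()
    depths = table.depths.to_numpy()
    n = table.n_donors
    counts = np.empty((b, len(cutoffs)), dtype=np.int64)
    for rep in range(b):
        idx = rng.integers(0, n, size=n)
        redrawn = rng.multinomial(depths[idx], props[idx])
        ab = redrawn / redrawn.sum(axis=1, keepdims=True)
        for j, c in enumerate(cutoffs):
            ub = (ab > c.abundance).mean(axis=0)
            counts[rep, j] = int((ub > c.ubiquity).sum())

    reports = []
    for j, c in enumerate(cutoffs):
        col = np.sort(counts[:, j])
        reports.append(
            CoreReport(
                cutoff=c,
                taxa=observed_sets[c],
                observed=len(observed_sets[c]),
                median=float(np.median(col)),
                lower=int(_nearest_rank(col, (1.0 - ci) / 2.0)),
                upper=int(_nearest_rank(col, 1.0 - (1.0 - ci) / 2.0)),
                b=b,
                ci=ci,
                seed=seed,
            )
        )
    return reports
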