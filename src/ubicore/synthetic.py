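"""Seeded generator of cohorts with planted core structure.

Each synthetic cohort has three taxon classes mirroring the structure the
analyses assume in real 16S profiles:

* **major core** — a handful of taxa at high base abundance, present in
  essentially every donor (the taxa a two-parameter cutoff like 1%|80%
  should elect);
* **minor core** — taxa at base abundance in [1e-4, 1e-2), present in a
  majority of donors but never exceeding the 1% ceiling;
* **sporadic** — a long power-law tail (rank-r base abundance
  proportional to r**-gamma) of taxa each present in a donor with
  probability q, carrying the interpersonal variability.

A donor is generated by (1) Bernoulli presence draws per class,
(2) multiplying each present taxon's base abundance by a lognormal
perturbation (Normal(0, sigma) on log10), (3) renormalizing to closure,
and (4) drawing the donor's reads as a single multinomial of its depth.
Read counts therefore carry exactly the sampling noise the binomial
detection model and the bootstrap procedures assume (simple random
sampling, no PCR amplification bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import TaxonCountTable, ValidationError

__all__ = ["SyntheticCohortSpec", "generate_cohort", "generate_pair"]

_DEF_MAJOR = (0.30, 0.20, 0.10, 0.05, 0.02)
_DEF_MINOR = tuple(np.geomspace(2e-4, 2e-3, 5))


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative parameters for a planted-structure cohort.

    Depth may be a single int (constant) or an inclusive (low, high)
    range sampled uniformly per donor.  ``sigma`` is the standard
    deviation of the per-donor Normal perturbation on log10 abundance.
    """

    n_donors: int = 100
    depth: int | tuple[int, int] = 5000
    major_abundances: tuple[float, ...] = _DEF_MAJOR
    major_presence: float = 1.0
    minor_abundances: tuple[float, ...] = _DEF_MINOR
    minor_presence: float = 0.8
    n_sporadic: int = 50
    sporadic_presence: float = 0.3
    gamma: float = 1.5
    sigma: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValidationError("need at least one donor")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"bad depth specification {self.depth!r}")
        for p, name in [
            (self.major_presence, "major_presence"),
            (self.minor_presence, "minor_presence"),
            (self.sporadic_presence, "sporadic_presence"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if any(a <= 0 for a in self.major_abundances):
            raise ValidationError("major base abundances must be positive")
        if any(not 1e-4 <= a < 1e-2 for a in self.minor_abundances):
            raise ValidationError("minor base abundances must lie in [1e-4, 1e-2)")
        if self.n_sporadic < 0 or self.sigma < 0:
            raise ValidationError("n_sporadic and sigma must be non-negative")
        if self.n_taxa == 0:
            raise ValidationError("spec generates no taxa")
        if sum(self.major_abundances) + sum(self.minor_abundances) >= 1.0 and self.n_sporadic > 0:
            raise ValidationError("major+minor base abundances leave no mass for sporadic taxa")

    @property
    def depth_range(self) -> tuple[int, int]:
        if isinstance(self.depth, tuple):
            return int(self.depth[0]), int(self.depth[1])
        return int(self.depth), int(self.depth)

    @property
    def n_taxa(self) -> int:
        return len(self.major_abundances) + len(self.minor_abundances) + self.n_sporadic

    @property
    def taxon_labels(self) -> list[str]:
        return (
            [f"major_{i + 1}" for i in range(len(self.major_abundances))]
            + [f"minor_{i + 1}" for i in range(len(self.minor_abundances))]
            + [f"sporadic_{i + 1}" for i in range(self.n_sporadic)]
        )

    @property
    def major_taxa(self) -> list[str]:
        return [f"major_{i + 1}" for i in range(len(self.major_abundances))]

    @property
    def minor_taxa(self) -> list[str]:
        return [f"minor_{i + 1}" for i in range(len(self.minor_abundances))]

    def base_abundances(self) -> np.ndarray:
        """Class base abundances; sporadic taxa share the leftover mass as
        a power law over ranks (rank r proportional to r**-gamma)."""
        major = np.asarray(self.major_abundances, dtype=float)
        minor = np.asarray(self.minor_abundances, dtype=float)
        leftover = 1.0 - major.sum() - minor.sum()
        if self.n_sporadic > 0:
            ranks = np.arange(1, self.n_sporadic + 1, dtype=float)
            tail = ranks ** (-self.gamma)
            sporadic = leftover * tail / tail.sum()
        else:
            sporadic = np.empty(0)
        return np.concatenate([major, minor, sporadic])

    def presence_probs(self) -> np.ndarray:
        return np.concatenate(
            [
                np.full(len(self.major_abundances), self.major_presence),
                np.full(len(self.minor_abundances), self.minor_presence),
                np.full(self.n_sporadic, self.sporadic_presence),
            ]
        )


def _generate_from_base(
    spec: SyntheticCohortSpec, base: np.ndarray, rng: np.random.Generator
) -> TaxonCountTable:
    probs = spec.presence_probs()
    lo, hi = spec.depth_range
    n, t = spec.n_donors, spec.n_taxa
    present = rng.random((n, t)) < probs
    noise = rng.normal(0.0, spec.sigma, size=(n, t))
    w = np.where(present, base * 10.0**noise, 0.0)
    # a donor with no present taxa carries no reads; force the top base taxon
    dead = w.sum(axis=1) == 0
    if dead.any():
        w[dead, int(np.argmax(base))] = base.max()
    p = w / w.sum(axis=1, keepdims=True)
    depths = rng.integers(lo, hi + 1, size=n) if hi > lo else np.full(n, lo)
    counts = rng.multinomial(depths, p)
    df = pd.DataFrame(
        counts, index=[f"donor_{i + 1}" for i in range(n)], columns=spec.taxon_labels
    )
    return TaxonCountTable(df)


def _generate(spec: SyntheticCohortSpec, rng: np.random.Generator) -> TaxonCountTable:
    lo, _ = spec.depth_range
    if spec.minor_abundances and lo < 1.0 / min(spec.minor_abundances):
        warnings.warn(
            f"depth {lo} cannot resolve the smallest minor-core abundance "
            f"{min(spec.minor_abundances):g}; minor-core recovery will be unreliable",
            stacklevel=3,
        )
    return _generate_from_base(spec, spec.base_abundances(), rng)


def generate_cohort(spec: SyntheticCohortSpec) -> TaxonCountTable:
    """Draw one cohort; deterministic under ``spec.seed``."""
    return _generate(spec, np.random.default_rng(spec.seed))


def generate_pair(
    spec: SyntheticCohortSpec, effect: dict[str, float] | None = None
) -> tuple[TaxonCountTable, TaxonCountTable]:
    """Draw two cohorts from the same spec with independent streams spawned
    from the master seed; ``effect`` maps taxon labels to fold-changes
    applied to cohort Y's base abundances before renormalization (identity
    effect gives exchangeable cohorts)."""
    effect = effect or {}
    labels = set(spec.taxon_labels)
    unknown = set(effect) - labels
    if unknown:
        raise ValidationError(f"effect names unknown taxa: {sorted(unknown)}")
    ss = np.random.SeedSequence(spec.seed)
    child_x, child_y = ss.spawn(2)
    x = _generate(spec, np.random.default_rng(child_x))

    if effect:
        # Fold-changes may push a minor taxon outside its class band, so
        # scale the base vector directly instead of re-entering the classed
        # constructor.
        base = spec.base_abundances()
        idx = {lab: j for j, lab in enumerate(spec.taxon_labels)}
        scaled = base.copy()
        for lab, fold in effect.items():
            scaled[idx[lab]] *= fold
        scaled /= scaled.sum()
        y = _generate_from_base(spec, scaled, np.random.default_rng(child_y))
    else:
        y = _generate(spec, np.random.default_rng(child_y))
    return x, y
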