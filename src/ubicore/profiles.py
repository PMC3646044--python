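"""Taxonomic count tables and compositional profiles.

A cohort is a set of donors, each with an integer vector of 16S read counts
over a shared taxon list (genus-level lineage strings or OTU identifiers).
Dividing each donor's counts by its read depth yields the compositional
profile (per-donor proportions summing to 1) on which ubiquity, core
election and cohort comparison operate.

Detection of a low-abundance taxon is a sampling question: a taxon at true
proportion ``p`` sequenced to depth ``n`` is missed entirely with
probability ``(1-p)**n``.  ``qualify_presence`` calls a taxon present only
when that miss probability is at most 5% (i.e. it would be re-detected in
at least 95% of resequencing runs of the same depth).
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Callable
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidationError",
    "ParseError",
    "TaxonCountTable",
    "CohortProfile",
    "DetectionModel",
    "read_count_table",
    "write_count_table",
    "collapse_rank",
    "normalize",
    "prob_no_detection",
    "binomial_pmf",
    "qualify_presence",
]

CLOSURE_TOL = 1e-12

DIALECTS = ("tsv_donors_by_taxa", "tsv_taxa_by_donors", "biom")


class ValidationError(ValueError):
    """Input data violates a contract (negative count, duplicate id, ...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def _check_unique(labels, what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


class TaxonCountTable:
    """Donors x taxa integer read counts.

    Wraps a pandas DataFrame (index = donor ids, columns = taxon labels,
    values = non-negative int64 read counts).  Depth of a donor is its row
    sum.  Construction validates; zero-depth donors are allowed here but
    are rejected by :func:`normalize` (the readers drop them with a
    warning at ingest).
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.shape[1] == 0:
            raise ValidationError("count table has no taxa")
        _check_unique(counts.index, "donor id")
        _check_unique(counts.columns, "taxon label")
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                raise ValidationError("counts must be integers (fractional or non-finite value found)")
            vals = vals.astype(np.int64)
        if np.any(vals < 0):
            raise ValidationError("counts must be non-negative")
        self._df = pd.DataFrame(
            vals.astype(np.int64),
            index=[str(i) for i in counts.index],
            columns=[str(c) for c in counts.columns],
        )

    # -- accessors ---------------------------------------------------------
    @property
    def donor_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def taxon_labels(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_donors(self) -> int:
        return self._df.shape[0]

    @property
    def n_taxa(self) -> int:
        return self._df.shape[1]

    @property
    def depths(self) -> pd.Series:
        """Reads per donor (row sums)."""
        return self._df.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    def drop_zero_depth(self) -> "TaxonCountTable":
        """Return a table without zero-depth donors, warning if any dropped."""
        depths = self.depths
        dead = depths.index[depths == 0]
        if len(dead) == 0:
            return self
        warnings.warn(
            f"dropping {len(dead)} zero-depth donor(s): {', '.join(map(str, dead[:5]))}"
            + ("..." if len(dead) > 5 else ""),
            stacklevel=2,
        )
        return TaxonCountTable(self._df.drop(index=dead))

    def normalize(self) -> "CohortProfile":
        return normalize(self)

    def equals(self, other: "TaxonCountTable") -> bool:
        return isinstance(other, TaxonCountTable) and self._df.equals(other._df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TaxonCountTable({self.n_donors} donors x {self.n_taxa} taxa)"


class CohortProfile:
    """Donors x taxa compositional abundances (each row sums to 1)."""

    def __init__(self, abundances: pd.DataFrame, depths: pd.Series | None = None):
        if abundances.shape[0] == 0 or abundances.shape[1] == 0:
            raise ValidationError("profile must have at least one donor and one taxon")
        _check_unique(abundances.index, "donor id")
        _check_unique(abundances.columns, "taxon label")
        vals = abundances.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValidationError("abundances must lie in [0, 1]")
        rows = vals.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            bad = abundances.index[np.argmax(np.abs(rows - 1.0))]
            raise ValidationError(f"abundances of donor {bad!r} do not sum to 1")
        self._df = pd.DataFrame(vals, index=list(abundances.index), columns=list(abundances.columns))
        if depths is None:
            depths = pd.Series(np.zeros(len(abundances), dtype=np.int64), index=self._df.index)
        self._depths = pd.Series(np.asarray(depths, dtype=np.int64), index=self._df.index)

    @property
    def donor_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def taxon_labels(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_donors(self) -> int:
        return self._df.shape[0]

    @property
    def depths(self) -> pd.Series:
        return self._depths.copy()

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    def abundance_vector(self, taxon: str) -> np.ndarray:
        """Per-donor abundances of one taxon (KeyError if unknown)."""
        return self._df[taxon].to_numpy()

    def mean_abundances(self) -> pd.Series:
        """Cohort-average abundance per taxon (zeros included)."""
        return self._df.mean(axis=0)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._df.columns

    def __repr__(self) -> str:  # pragma: no cover
        return f"CohortProfile({self._df.shape[0]} donors x {self._df.shape[1]} taxa)"


def normalize(table: TaxonCountTable) -> CohortProfile:
    """Row-normalize counts to per-donor proportions (compositional closure).

    Every donor must have depth >= 1; zero-depth donors should have been
    dropped at read time.
    """
    depths = table.depths
    if (depths == 0).any():
        bad = depths.index[depths == 0][0]
        raise ValidationError(f"donor {bad!r} has zero depth; drop it before normalizing")
    ab = table.to_frame().div(depths, axis=0)
    return CohortProfile(ab, depths)


# ---------------------------------------------------------------------------
# I/O


def _parse_tsv(path: str) -> tuple[list[str], list[str], np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}, line 1: header must contain at least one taxon column")
    col_labels = header[1:]
    row_labels: list[str] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}, line {lineno}: expected {len(header)} fields, found {len(fields)}"
            )
        row_labels.append(fields[0])
        row: list[int] = []
        for lab, f in zip(col_labels, fields[1:]):
            try:
                v = int(f)
            except ValueError:
                raise ValidationError(
                    f"{path}, line {lineno}: count {f!r} for {lab!r} is not an integer"
                ) from None
            if v < 0:
                raise ValidationError(f"{path}, line {lineno}: negative count {v} for {lab!r}")
            row.append(v)
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return row_labels, col_labels, np.asarray(rows, dtype=np.int64)


def _read_biom(path: str) -> pd.DataFrame:
    """Minimal BIOM 1.0 (JSON) reader; rows are observations (taxa), columns samples."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        taxa = [r["id"] for r in doc["rows"]]
        donors = [c["id"] for c in doc["columns"]]
        mtype = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: not a BIOM 1.0 JSON table ({exc})") from None
    mat = np.zeros((len(taxa), len(donors)), dtype=np.int64)
    if mtype == "dense":
        mat[:, :] = np.asarray(data)
    elif mtype == "sparse":
        for r, c, v in data:
            mat[int(r), int(c)] = v
    else:
        raise ParseError(f"{path}: unsupported matrix_type {mtype!r}")
    return pd.DataFrame(mat.T, index=donors, columns=taxa)


def read_count_table(path: str, dialect: str = "tsv_donors_by_taxa") -> TaxonCountTable:
    """Read a count table; zero-depth donors are dropped with a warning.

    Dialects: ``tsv_donors_by_taxa`` (canonical; first column donor id,
    header = taxon labels), ``tsv_taxa_by_donors`` (transposed), ``biom``
    (BIOM 1.0 JSON, dense or sparse).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "biom":
        df = _read_biom(path)
    else:
        row_labels, col_labels, mat = _parse_tsv(path)
        df = pd.DataFrame(mat, index=row_labels, columns=col_labels)
        if dialect == "tsv_taxa_by_donors":
            df = df.T
    return TaxonCountTable(df).drop_zero_depth()


def write_count_table(table: TaxonCountTable, path: str) -> None:
    """Write the canonical dialect: donors as rows, lexicographically sorted
    taxa, UTF-8, Unix newlines."""
    df = table.to_frame()
    df = df[sorted(df.columns)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("donor\t" + "\t".join(df.columns) + "\n")
        for donor, row in zip(df.index, df.to_numpy()):
            fh.write(str(donor) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def collapse_rank(table: TaxonCountTable, rank_extractor: Callable[[str], str]) -> TaxonCountTable:
    """Sum counts of taxa sharing a group label (e.g. OTUs into a genus).

    ``rank_extractor`` maps each taxon label to its group label; depths are
    conserved.  An empty group label is an error.
    """
    groups: dict[str, list[str]] = {}
    for lab in table.taxon_labels:
        g = rank_extractor(lab)
        if not g:
            raise ValidationError(f"rank extractor returned an empty label for {lab!r}")
        groups.setdefault(str(g), []).append(lab)
    df = table.to_frame()
    out = pd.DataFrame(
        {g: df[cols].sum(axis=1) for g, cols in groups.items()},
        index=df.index,
    )
    return TaxonCountTable(out)


# ---------------------------------------------------------------------------
# Binomial detection qualification


@dataclass(frozen=True)
class DetectionModel:
    """Binomial model of detecting a taxon at proportion ``p`` in ``n`` reads."""

    p: float
    n: int
    k: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p={self.p} outside [0, 1]")
        if self.n < 1:
            raise ValidationError(f"n={self.n} must be >= 1")
        if not 0 <= self.k <= self.n:
            raise ValidationError(f"k={self.k} outside [0, n={self.n}]")

    def pmf(self) -> float:
        return binomial_pmf(self.k, self.n, self.p)

    def prob_no_detection(self) -> float:
        return prob_no_detection(self.p, self.n)


def prob_no_detection(p: float, n: int) -> float:
    """Probability of zero reads for a taxon at proportion ``p``, depth ``n``:
    ``(1-p)**n``."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p={p} outside [0, 1]")
    if n < 0 or int(n) != n:
        raise ValidationError(f"n={n} must be a non-negative integer")
    return float((1.0 - p) ** int(n))


def binomial_pmf(k: int, n: int, p: float) -> float:
    """P(K = k) for K ~ Binomial(n, p)."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p={p} outside [0, 1]")
    if not 0 <= k <= n:
        raise ValidationError(f"k={k} outside [0, n={n}]")
    return float(stats.binom.pmf(k, n, p))


def qualify_presence(p: float, n: int, miss_threshold: float = 0.05) -> bool:
    """Call a taxon present iff it would be re-detected in at least
    ``1 - miss_threshold`` of resequencing runs at the same depth, i.e.
    ``(1-p)**n <= miss_threshold``."""
    return prob_no_detection(p, n) <= miss_threshold
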