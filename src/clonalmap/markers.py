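"""Marker categories, genotype matrices, and two-locus scenario classification.

A clonal F1 population is the progeny of a cross between two heterozygous,
vegetatively propagated parents.  Each locus may segregate for up to four
alleles: ``A``/``B`` in the female parent and ``C``/``D`` in the male parent.
Markers are classified by how many of those alleles are distinguishable:

========  =========  ==========================  ==================
category  mnemonic   identifiable genotypes      Mendelian ratio
========  =========  ==========================  ==================
I         ABCD       AC, AD, BC, BD              1:1:1:1
II        A=B        XC, XD                      1:1
III       C=D        AX, BX                      1:1
IV        AB=CD      AA, AB, BB                  1:2:1
V         A=D,B=C    AA, AB, BB                  1:2:1
========  =========  ==========================  ==================

Category V only exists in a phase-known double cross (a four-way cross with
genotyped founders), where the co-dominant pattern of category IV can be
split by whether allele ``A`` matches founder allele ``C`` (category IV) or
founder allele ``D`` (category V).  Missing genotypes are coded ``XX``.

For a pair of loci, the category combination determines which recombination
frequencies (female ``r_F``, male ``r_M``, combined ``r``) are estimable.
The fourteen estimable combinations are numbered scenarios 1-14; a II-III
pair carries no linkage information at all and maps to scenario ``None``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = "XX"


class MarkerCategory(enum.IntEnum):
    """Marker polymorphism category (ordering used to canonicalize pairs)."""

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5

    @classmethod
    def parse(cls, label: str) -> "MarkerCategory":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown marker category {label!r}") from None


class PopulationType(enum.Enum):
    CLONAL_F1 = "clonal_F1"
    DOUBLE_CROSS = "double_cross_phase_known"

    @classmethod
    def parse(cls, label: "str | PopulationType") -> "PopulationType":
        if isinstance(label, cls):
            return label
        for member in cls:
            if member.value == label or member.name.lower() == str(label).lower():
                return member
        raise ValueError(f"unknown population type {label!r}")


#: Legal genotype codes per category (XX is legal everywhere).
CATEGORY_CODES: dict[MarkerCategory, tuple[str, ...]] = {
    MarkerCategory.I: ("AC", "AD", "BC", "BD"),
    MarkerCategory.II: ("XC", "XD"),
    MarkerCategory.III: ("AX", "BX"),
    MarkerCategory.IV: ("AA", "AB", "BB"),
    MarkerCategory.V: ("AA", "AB", "BB"),
}

#: Expected Mendelian ratios, in the order of CATEGORY_CODES.
CATEGORY_RATIOS: dict[MarkerCategory, tuple[float, ...]] = {
    MarkerCategory.I: (0.25, 0.25, 0.25, 0.25),
    MarkerCategory.II: (0.5, 0.5),
    MarkerCategory.III: (0.5, 0.5),
    MarkerCategory.IV: (0.25, 0.5, 0.25),
    MarkerCategory.V: (0.25, 0.5, 0.25),
}


class InvalidInputError(ValueError):
    """Raised on malformed genotype data or illegal category/population combos."""


@dataclass(frozen=True)
class Scenario:
    """A two-locus estimation scenario (canonical orientation: cat1 <= cat2).

    ``id`` is 1-9 for clonal F1 pairs, 10-14 for double-cross pairs
    involving category V, or ``None`` for the uninformative II-III pair.
    ``swapped`` records whether the input pair was reversed to reach the
    canonical orientation.  ``est_rf``/``est_rm`` mark direct estimability
    of the parental recombination frequencies; the combined ``r`` is
    defined for every non-``None`` scenario.
    """

    id: int | None
    cat1: MarkerCategory
    cat2: MarkerCategory
    swapped: bool
    est_rf: bool
    est_rm: bool

    @property
    def estimable(self) -> bool:
        return self.id is not None


# (canonical category pair) -> (scenario id, rF estimable, rM estimable)
_SCENARIO_TABLE: dict[tuple[MarkerCategory, MarkerCategory], tuple[int | None, bool, bool]] = {
    (MarkerCategory.I, MarkerCategory.I): (1, True, True),
    (MarkerCategory.I, MarkerCategory.II): (2, False, True),
    (MarkerCategory.I, MarkerCategory.III): (3, True, False),
    (MarkerCategory.I, MarkerCategory.IV): (4, True, True),
    (MarkerCategory.II, MarkerCategory.II): (5, False, True),
    (MarkerCategory.II, MarkerCategory.III): (None, False, False),
    (MarkerCategory.II, MarkerCategory.IV): (6, False, True),
    (MarkerCategory.III, MarkerCategory.III): (7, True, False),
    (MarkerCategory.III, MarkerCategory.IV): (8, True, False),
    (MarkerCategory.IV, MarkerCategory.IV): (9, False, False),
    (MarkerCategory.I, MarkerCategory.V): (10, True, True),
    (MarkerCategory.II, MarkerCategory.V): (11, False, True),
    (MarkerCategory.III, MarkerCategory.V): (12, True, False),
    (MarkerCategory.IV, MarkerCategory.V): (13, False, False),
    (MarkerCategory.V, MarkerCategory.V): (14, False, False),
}


def classify_pair(
    cat1: MarkerCategory,
    cat2: MarkerCategory,
    pop: PopulationType = PopulationType.CLONAL_F1,
) -> Scenario:
    """Classify a marker pair into its estimation scenario.

    The pair is canonicalized so the lower-numbered category is locus 1
    (the two orientations are symmetric).  Category V is only legal in a
    phase-known double cross.
    """
    cat1 = MarkerCategory(cat1)
    cat2 = MarkerCategory(cat2)
    if pop is PopulationType.CLONAL_F1 and MarkerCategory.V in (cat1, cat2):
        raise InvalidInputError("category V markers require a phase-known double cross")
    swapped = cat2 < cat1
    a, b = (cat2, cat1) if swapped else (cat1, cat2)
    sid, est_rf, est_rm = _SCENARIO_TABLE[(a, b)]
    return Scenario(id=sid, cat1=a, cat2=b, swapped=swapped, est_rf=est_rf, est_rm=est_rm)


@dataclass(frozen=True)
class SegregationResult:
    chi2: float
    df: int
    p: float
    distorted: bool
    counts: tuple[int, ...]


def segregation_test(
    column: Sequence[str],
    category: MarkerCategory,
    alpha: float = 0.05,
) -> SegregationResult:
    """Chi-square goodness-of-fit of one marker against its Mendelian ratio.

    Missing (``XX``) cells are excluded.  Uses the asymptotic chi-square
    distribution without continuity correction.
    """
    category = MarkerCategory(category)
    codes = CATEGORY_CODES[category]
    observed = pd.Series(list(column))
    observed = observed[observed != MISSING]
    if observed.empty:
        raise InvalidInputError("segregation test undefined: all genotypes missing")
    bad = set(observed) - set(codes)
    if bad:
        raise InvalidInputError(
            f"genotype codes {sorted(bad)} illegal for category {category.name}"
        )
    counts = np.array([int((observed == c).sum()) for c in codes])
    expected = np.asarray(CATEGORY_RATIOS[category]) * counts.sum()
    chi2, p = stats.chisquare(counts, expected)
    return SegregationResult(
        chi2=float(chi2),
        df=len(codes) - 1,
        p=float(p),
        distorted=bool(p < alpha),
        counts=tuple(int(c) for c in counts),
    )


@dataclass
class GenotypeMatrix:
    """A genotype table of m markers x n progenies.

    ``codes`` is a DataFrame indexed by marker id with one column per
    progeny; every cell is a genotype code legal for the marker's category,
    or ``XX``.
    """

    categories: dict[str, MarkerCategory]
    codes: pd.DataFrame
    population: PopulationType = PopulationType.CLONAL_F1

    def __post_init__(self) -> None:
        self.validate()

    @property
    def marker_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def progeny_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def n_progenies(self) -> int:
        return self.codes.shape[1]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[0]

    def category(self, marker: str) -> MarkerCategory:
        return self.categories[marker]

    def validate(self) -> None:
        if self.codes.shape[0] < 2:
            raise InvalidInputError("need at least 2 markers")
        if self.codes.shape[1] < 1:
            raise InvalidInputError("need at least 1 progeny")
        if set(self.codes.index) != set(self.categories):
            raise InvalidInputError("marker ids in codes and categories differ")
        if self.codes.index.has_duplicates:
            raise InvalidInputError("duplicate marker ids")
        for marker, cat in self.categories.items():
            if cat is MarkerCategory.V and self.population is PopulationType.CLONAL_F1:
                raise InvalidInputError(
                    f"marker {marker!r}: category V illegal in a clonal F1 population"
                )
            legal = set(CATEGORY_CODES[cat]) | {MISSING}
            bad = set(self.codes.loc[marker]) - legal
            if bad:
                raise InvalidInputError(
                    f"marker {marker!r} (category {cat.name}): illegal codes {sorted(bad)}"
                )

    def segregation_screen(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-marker segregation-distortion screen (markers are flagged, not dropped)."""
        rows = []
        for marker in self.marker_ids:
            res = segregation_test(self.codes.loc[marker], self.categories[marker], alpha)
            rows.append(
                {
                    "marker": marker,
                    "category": self.categories[marker].name,
                    "chi2": res.chi2,
                    "df": res.df,
                    "p": res.p,
                    "distorted": res.distorted,
                }
            )
        return pd.DataFrame(rows).set_index("marker")


# ---------------------------------------------------------------------------
# Joint genotype classes per scenario
# ---------------------------------------------------------------------------
# Class order follows the published two-locus frequency tables: n_1 ... n_k.

_I = CATEGORY_CODES[MarkerCategory.I]
_AA = ("AA", "AB", "BB")

#: scenario id -> ordered (locus-1 code, locus-2 code) genotype classes
SCENARIO_CLASSES: dict[int, tuple[tuple[str, str], ...]] = {
    1: (
        ("AC", "AC"), ("AC", "AD"), ("AD", "AC"), ("AD", "AD"),
        ("AC", "BC"), ("AC", "BD"), ("AD", "BC"), ("AD", "BD"),
        ("BC", "AC"), ("BC", "AD"), ("BD", "AC"), ("BD", "AD"),
        ("BC", "BC"), ("BC", "BD"), ("BD", "BC"), ("BD", "BD"),
    ),
    2: tuple((g1, g2) for g1 in _I for g2 in ("XC", "XD")),
    3: tuple((g1, g2) for g1 in _I for g2 in ("AX", "BX")),
    4: tuple((g1, g2) for g1 in _I for g2 in _AA),
    5: tuple((g1, g2) for g1 in ("XC", "XD") for g2 in ("XC", "XD")),
    6: tuple((g1, g2) for g1 in ("XC", "XD") for g2 in _AA),
    7: tuple((g1, g2) for g1 in ("AX", "BX") for g2 in ("AX", "BX")),
    8: tuple((g1, g2) for g1 in ("AX", "BX") for g2 in _AA),
    9: tuple((g1, g2) for g1 in _AA for g2 in _AA),
}
# Double-cross scenarios share class layouts with their clonal counterparts.
SCENARIO_CLASSES[10] = SCENARIO_CLASSES[4]
SCENARIO_CLASSES[11] = SCENARIO_CLASSES[6]
SCENARIO_CLASSES[12] = SCENARIO_CLASSES[8]
SCENARIO_CLASSES[13] = SCENARIO_CLASSES[9]
SCENARIO_CLASSES[14] = SCENARIO_CLASSES[9]


@dataclass(frozen=True)
class JointCounts:
    """Ordered genotype-class counts for one marker pair under a scenario."""

    scenario: Scenario
    counts: tuple[int, ...]
    n_missing: int = 0

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def joint_counts(
    col1: Sequence[str],
    col2: Sequence[str],
    scenario: Scenario,
) -> JointCounts:
    """Tabulate joint genotype classes for a marker pair.

    Progenies missing (``XX``) at either locus are excluded (pairwise
    deletion).  Columns are given in input order; if the scenario was
    canonicalized by swapping the pair, the columns are swapped to match.
    """
    if scenario.id is None:
        raise InvalidInputError("joint counts undefined for a non-estimable pair")
    if scenario.swapped:
        col1, col2 = col2, col1
    classes = SCENARIO_CLASSES[scenario.id]
    index = {pair: k for k, pair in enumerate(classes)}
    counts = [0] * len(classes)
    missing = 0
    for g1, g2 in zip(col1, col2, strict=True):
        if g1 == MISSING or g2 == MISSING:
            missing += 1
            continue
        try:
            counts[index[(g1, g2)]] += 1
        except KeyError:
            raise InvalidInputError(
                f"genotype pair ({g1!r}, {g2!r}) illegal for scenario {scenario.id}"
            ) from None
    return JointCounts(scenario=scenario, counts=tuple(counts), n_missing=missing)


# ---------------------------------------------------------------------------
# Delimited text I/O
# ---------------------------------------------------------------------------

def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_genotype_file(
    path: str | Path,
    population: PopulationType | str = PopulationType.CLONAL_F1,
) -> GenotypeMatrix:
    """Read a genotype table from delimited text.

    Layout: row 1 = header (``marker``, ``category``, progeny ids);
    each following row = marker id, category label, genotype codes.
    Errors are reported with line and column numbers.
    """
    path = Path(path)
    population = PopulationType.parse(population)
    sep = _delimiter_for(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise InvalidInputError(f"{path}: empty file")
    header = [c.strip() for c in lines[0].split(sep)]
    if len(header) < 3:
        raise InvalidInputError(f"{path}:1: header needs marker, category, >=1 progeny")
    progeny_ids = header[2:]
    categories: dict[str, MarkerCategory] = {}
    rows: dict[str, list[str]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = [c.strip() for c in line.split(sep)]
        if len(cells) != len(header):
            raise InvalidInputError(
                f"{path}:{lineno}: expected {len(header)} fields, found {len(cells)}"
            )
        marker = cells[0]
        if marker in categories:
            raise InvalidInputError(f"{path}:{lineno}: duplicate marker id {marker!r}")
        try:
            cat = MarkerCategory.parse(cells[1])
        except ValueError as exc:
            raise InvalidInputError(f"{path}:{lineno}: column 2: {exc}") from None
        legal = set(CATEGORY_CODES[cat]) | {MISSING}
        for col, code in enumerate(cells[2:], start=3):
            if code not in legal:
                raise InvalidInputError(
                    f"{path}:{lineno}: column {col}: code {code!r} illegal for "
                    f"category {cat.name}"
                )
        categories[marker] = cat
        rows[marker] = cells[2:]
    codes = pd.DataFrame.from_dict(rows, orient="index", columns=progeny_ids)
    return GenotypeMatrix(categories=categories, codes=codes, population=population)


def write_genotype_file(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype table in the delimited text layout of :func:`read_genotype_file`."""
    path = Path(path)
    sep = _delimiter_for(path)
    with path.open("w") as fh:
        fh.write(sep.join(["marker", "category", *gm.progeny_ids]) + "\n")
        for marker in gm.marker_ids:
            row = [marker, gm.categories[marker].name, *gm.codes.loc[marker]]
            fh.write(sep.join(row) + "\n")
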