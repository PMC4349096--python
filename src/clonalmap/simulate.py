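"""Simulation of clonal F1 and double-cross populations with known truth.

Each progeny is the union of one female and one male gamete.  Gametes are
drawn by a Markov walk along the chromosome with no crossover interference
(the Haldane model): the starting homologue is uniform and the walk
switches homologue between loci i and i+1 with the adjacent recombination
frequency r_i.  Observed genotype codes collapse the underlying four-allele
genotypes according to each marker's category, unknown linkage phases are
induced by per-marker allele-label swaps in the parents, missingness is
independent per cell, and segregation distortion (optional) acts through
viability weights by rejection sampling.

The bundled ``demo20`` design is a single chromosome of 20 markers at
adjacent r = 0.05 (5.27 cM Haldane) with five markers in each category,
the co-dominant markers split between the A=C,B=D and A=D,B=C patterns,
and a fixed pattern of parental label swaps, genotyped in 200 progenies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import GenotypeMatrix, MarkerCategory, PopulationType


@dataclass
class SimulationConfig:
    """Design of one simulated chromosome.

    ``adjacent_r`` has one entry per neighbouring marker pair, each in
    [0, 0.5).  ``iv_pattern`` distinguishes the two co-dominant allele
    matchings for category-IV markers ("AC" = A=C,B=D; "AD" = A=D,B=C);
    it is ignored for other categories.  ``female_swap``/``male_swap``
    exchange the parental allele labels at a marker, simulating unknown
    linkage phase.  ``viability`` optionally maps marker id -> (genotype
    code -> relative viability in (0, 1]) to induce segregation distortion.
    """

    categories: list[MarkerCategory]
    adjacent_r: list[float]
    n: int = 200
    marker_ids: list[str] | None = None
    iv_pattern: dict[int, str] = field(default_factory=dict)
    female_swap: set[int] = field(default_factory=set)
    male_swap: set[int] = field(default_factory=set)
    missing_rate: float = 0.0
    viability: dict[str, dict[str, float]] = field(default_factory=dict)
    population: PopulationType = PopulationType.CLONAL_F1

    def __post_init__(self) -> None:
        m = len(self.categories)
        if m < 2:
            raise ValueError("need at least 2 markers")
        if len(self.adjacent_r) != m - 1:
            raise ValueError("adjacent_r must have one entry per marker interval")
        if any(not 0.0 <= r < 0.5 for r in self.adjacent_r):
            raise ValueError("adjacent recombination frequencies must be in [0, 0.5)")
        if self.n < 1:
            raise ValueError("need at least 1 progeny")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")
        if self.marker_ids is None:
            self.marker_ids = [f"M{k + 1}" for k in range(m)]
        if (
            self.population is PopulationType.CLONAL_F1
            and MarkerCategory.V in self.categories
        ):
            raise ValueError("category V requires a double-cross population")

    @property
    def m(self) -> int:
        return len(self.categories)


@dataclass
class TruthRecord:
    """Ground truth of a simulated population.

    ``hap_a`` .. ``hap_d`` give, per marker, the allele label carried by
    each parental haploid in the reporting convention of the haploid
    builder (for co-dominant markers, male C = the A pattern).  ``true_r``
    is the m x m matrix of pairwise recombination frequencies implied by
    the adjacent values under no interference (identical in both parents).
    """

    marker_ids: list[str]
    categories: list[MarkerCategory]
    hap_a: list[str]
    hap_b: list[str]
    hap_c: list[str]
    hap_d: list[str]
    true_r: pd.DataFrame
    adjacent_r: list[float]

    def haploid_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": [c.name for c in self.categories],
                "hap_a": self.hap_a,
                "hap_b": self.hap_b,
                "hap_c": self.hap_c,
                "hap_d": self.hap_d,
            },
            index=pd.Index(self.marker_ids, name="marker"),
        )


def pairwise_r(adjacent_r: list[float]) -> np.ndarray:
    """Combine adjacent recombination frequencies under no interference.

    r_ij = (1 - prod(1 - 2 r_k)) / 2 over the intervening intervals.
    """
    m = len(adjacent_r) + 1
    out = np.zeros((m, m))
    factors = 1.0 - 2.0 * np.asarray(adjacent_r)
    for i in range(m):
        prod = 1.0
        for j in range(i + 1, m):
            prod *= factors[j - 1]
            out[i, j] = out[j, i] = 0.5 * (1.0 - prod)
    return out


def simulate_gamete(
    adjacent_r: list[float],
    rng: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Draw homologue indicators (0/1 per locus) for n gametes.

    Strand 0/1 is the parent's first/second haploid; the walk starts
    uniformly and switches between consecutive loci with probability r_i.
    """
    m = len(adjacent_r) + 1
    strands = np.empty((n, m), dtype=np.int8)
    strands[:, 0] = rng.integers(0, 2, size=n)
    for k, r in enumerate(adjacent_r):
        switch = rng.random(n) < r
        strands[:, k + 1] = np.where(switch, 1 - strands[:, k], strands[:, k])
    return strands


def _truth(cfg: SimulationConfig) -> TruthRecord:
    hap_a, hap_b, hap_c, hap_d = [], [], [], []
    for k, cat in enumerate(cfg.categories):
        fs = k in cfg.female_swap
        ms = k in cfg.male_swap
        if cat is MarkerCategory.II:
            a = b = "X"
        else:
            a, b = ("B", "A") if fs else ("A", "B")
        if cat is MarkerCategory.III:
            c = d = "X"
        elif cat in (MarkerCategory.IV, MarkerCategory.V):
            # male haploid 1 carries C or D; report whether its allele is
            # the A pattern ("C") or the B pattern ("D")
            pattern_map = _iv_pattern_map(cfg, k)
            first = pattern_map["D" if ms else "C"]
            c, d = ("C", "D") if first == "A" else ("D", "C")
        else:
            c, d = ("D", "C") if ms else ("C", "D")
        hap_a.append(a)
        hap_b.append(b)
        hap_c.append(c)
        hap_d.append(d)
    rr = pairwise_r(cfg.adjacent_r)
    true_r = pd.DataFrame(rr, index=cfg.marker_ids, columns=cfg.marker_ids)
    return TruthRecord(
        marker_ids=list(cfg.marker_ids),
        categories=list(cfg.categories),
        hap_a=hap_a, hap_b=hap_b, hap_c=hap_c, hap_d=hap_d,
        true_r=true_r,
        adjacent_r=list(cfg.adjacent_r),
    )


def _iv_pattern_map(cfg: SimulationConfig, k: int) -> dict[str, str]:
    """Male allele -> A/B pattern for a co-dominant marker."""
    cat = cfg.categories[k]
    pattern = cfg.iv_pattern.get(k, "AC")
    if cat is MarkerCategory.V:
        pattern = "AD"
    return {"C": "A", "D": "B"} if pattern == "AC" else {"C": "B", "D": "A"}


def _encode(
    cfg: SimulationConfig,
    k: int,
    female_allele: str,
    male_allele: str,
) -> str:
    cat = cfg.categories[k]
    if cat is MarkerCategory.I:
        return female_allele + male_allele
    if cat is MarkerCategory.II:
        return "X" + male_allele
    if cat is MarkerCategory.III:
        return female_allele + "X"
    male_pattern = _iv_pattern_map(cfg, k)[male_allele]
    return "".join(sorted(female_allele + male_pattern))


def simulate_population(
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate a genotyped population and return it with its ground truth."""
    rng = np.random.default_rng(rng)
    truth = _truth(cfg)
    m = cfg.m

    # parental haploids as allele labels, ordered (haploid 1, haploid 2)
    female_h = []
    male_h = []
    for k in range(m):
        fa = ("B", "A") if k in cfg.female_swap else ("A", "B")
        ma = ("D", "C") if k in cfg.male_swap else ("C", "D")
        female_h.append(fa)
        male_h.append(ma)

    def draw_block(count: int) -> list[list[str]]:
        fg = simulate_gamete(cfg.adjacent_r, rng, count)
        mg = simulate_gamete(cfg.adjacent_r, rng, count)
        block = []
        for i in range(count):
            block.append(
                [
                    _encode(cfg, k, female_h[k][fg[i, k]], male_h[k][mg[i, k]])
                    for k in range(m)
                ]
            )
        return block

    progenies: list[list[str]] = []
    max_w = {
        mk: max(1.0, *w.values()) for mk, w in cfg.viability.items()
    }
    while len(progenies) < cfg.n:
        block = draw_block(cfg.n - len(progenies))
        if not cfg.viability:
            progenies.extend(block)
            continue
        for row in block:  # rejection sampling on relative viability
            keep = True
            for mk, weights in cfg.viability.items():
                k = cfg.marker_ids.index(mk)
                w = weights.get(row[k], 1.0) / max_w[mk]
                if rng.random() >= w:
                    keep = False
                    break
            if keep:
                progenies.append(row)

    codes = np.array(progenies, dtype=object).T  # markers x progenies
    if cfg.missing_rate > 0:
        miss = rng.random(codes.shape) < cfg.missing_rate
        codes[miss] = "XX"
    df = pd.DataFrame(
        codes,
        index=cfg.marker_ids,
        columns=[f"P{i + 1}" for i in range(cfg.n)],
    )
    gm = GenotypeMatrix(
        categories=dict(zip(cfg.marker_ids, cfg.categories)),
        codes=df,
        population=cfg.population,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def demo20_config(
    n: int = 200,
    missing_rate: float = 0.0,
    adjacent_r: float = 0.05,
) -> SimulationConfig:
    """The 20-marker, one-chromosome reference design.

    Markers 8, 11, 14, 17, 19 are category I; 1, 2, 13, 15, 20 category II;
    4, 5, 7, 9, 18 category III; 10, 12 co-dominant with A=C,B=D and
    3, 6, 16 co-dominant with A=D,B=C.  Alleles A/B are swapped at markers
    5, 8, 12, 16, 18 and C/D at markers 8, 12, 14, 15, 16, 20 to simulate
    unknown linkage phases.
    """
    cat = {}
    for k in (8, 11, 14, 17, 19):
        cat[k] = MarkerCategory.I
    for k in (1, 2, 13, 15, 20):
        cat[k] = MarkerCategory.II
    for k in (4, 5, 7, 9, 18):
        cat[k] = MarkerCategory.III
    for k in (3, 6, 10, 12, 16):
        cat[k] = MarkerCategory.IV
    categories = [cat[k] for k in range(1, 21)]
    iv_pattern = {k - 1: "AC" for k in (10, 12)}
    iv_pattern.update({k - 1: "AD" for k in (3, 6, 16)})
    return SimulationConfig(
        categories=categories,
        adjacent_r=[adjacent_r] * 19,
        n=n,
        marker_ids=[f"M{k}" for k in range(1, 21)],
        iv_pattern=iv_pattern,
        female_swap={k - 1 for k in (5, 8, 12, 16, 18)},
        male_swap={k - 1 for k in (8, 12, 14, 15, 16, 20)},
        missing_rate=missing_rate,
    )


PRESETS = {"demo20": demo20_config}
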