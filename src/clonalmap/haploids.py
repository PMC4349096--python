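"""Reconstruction of the four parental haploids from an ordered linkage map.

A clonal F1's parents are heterozygous with unknown linkage phase: the
female parent carries haploids HapA/HapB, the male parent HapC/HapD, and
which allele sits on which haploid must be inferred.  Walking each parental
map in order, the allele arrangement at a locus relative to the previous
locus is read off the raw parental recombination estimate between them: an
estimate below 0.5 keeps the current orientation, above 0.5 flips it, and
flips compose along the chain.

Once built, category-IV (co-dominant) markers can be split by whether the
allele pattern on HapA matches the one on HapC (category IV of a double
cross) or on HapD (category V), and the whole population can be relabelled
so HapA carries ``A`` and HapC carries ``C`` at every locus: the clonal F1
then is, exactly, a phase-known double cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .estimation import RecombMatrix
from .markers import GenotypeMatrix, MarkerCategory, PopulationType

_X = "X"


@dataclass
class HaploidSet:
    """Per-marker allele assignments for HapA/HapB (female) and HapC/HapD (male).

    ``table`` is indexed by marker id in map order with columns
    ``category``, ``hap_a``, ``hap_b``, ``hap_c``, ``hap_d``,
    ``updated_category``, ``female_ambiguous``, ``male_ambiguous``.
    For category-IV/V markers the male entries use the convention that
    ``C`` denotes the male copy of the A pattern and ``D`` the B pattern.
    """

    table: pd.DataFrame

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table.index)


def _chain_orientations(
    markers: list[str],
    chain_r: list[float],
) -> tuple[list[bool], list[bool]]:
    """Compose flips along one parental chain.

    Returns per-marker ``flipped`` state and an ``ambiguous`` flag for loci
    whose chain estimate was missing or exactly 0.5 (orientation kept,
    flagged, so builds stay reproducible).
    """
    flipped = [False]
    ambiguous = [False]
    state = False
    for r in chain_r:
        if r is None or math.isnan(r):
            ambiguous.append(True)
        elif abs(r - 0.5) < 1e-12:
            ambiguous.append(True)
        else:
            ambiguous.append(False)
            if r > 0.5:
                state = not state
        flipped.append(state)
    assert len(flipped) == len(markers)
    return flipped, ambiguous


def build_parent_haploids(
    parent_markers: list[str],
    chain_r: list[float],
    alleles: tuple[str, str],
) -> pd.DataFrame:
    """Assign alleles to one parent's two haploids along its map.

    ``chain_r`` holds the raw recombination estimate between each pair of
    consecutive markers (length ``len(parent_markers) - 1``).  At the first
    locus the first allele goes to the first haploid; afterwards each flip
    follows the sign of (r - 0.5) relative to the previous locus.
    """
    first, second = alleles
    flipped, ambiguous = _chain_orientations(parent_markers, chain_r)
    rows = {
        m: (second, first) if fl else (first, second)
        for m, fl in zip(parent_markers, flipped)
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["hap1", "hap2"])
    df["ambiguous"] = ambiguous
    return df


def build_haploids(order: list[str], rm: RecombMatrix) -> HaploidSet:
    """Build all four haploids for one ordered linkage group.

    The female chain walks the combined order restricted to markers
    polymorphic in the female parent (category II skipped) using raw
    ``r_F``; the male chain skips category III and uses raw ``r_M``.
    """
    cats = {m: rm.category(m) for m in order}
    female_markers = [m for m in order if cats[m] is not MarkerCategory.II]
    male_markers = [m for m in order if cats[m] is not MarkerCategory.III]
    f_chain = [
        float(rm.r_f.loc[a, b])
        for a, b in zip(female_markers, female_markers[1:])
    ]
    m_chain = [
        float(rm.r_m.loc[a, b])
        for a, b in zip(male_markers, male_markers[1:])
    ]
    female = build_parent_haploids(female_markers, f_chain, ("A", "B"))
    male = build_parent_haploids(male_markers, m_chain, ("C", "D"))

    rows = []
    for m in order:
        cat = cats[m]
        if cat is MarkerCategory.II:
            hap_a = hap_b = _X
            f_amb = False
        else:
            hap_a, hap_b = female.loc[m, "hap1"], female.loc[m, "hap2"]
            f_amb = bool(female.loc[m, "ambiguous"])
        if cat is MarkerCategory.III:
            hap_c = hap_d = _X
            m_amb = False
        else:
            hap_c, hap_d = male.loc[m, "hap1"], male.loc[m, "hap2"]
            m_amb = bool(male.loc[m, "ambiguous"])
        rows.append(
            {
                "marker": m,
                "category": cat.name,
                "hap_a": hap_a,
                "hap_b": hap_b,
                "hap_c": hap_c,
                "hap_d": hap_d,
                "updated_category": cat.name,
                "female_ambiguous": f_amb,
                "male_ambiguous": m_amb,
            }
        )
    hs = HaploidSet(table=pd.DataFrame(rows).set_index("marker"))
    return update_categories(hs)


def update_categories(hs: HaploidSet) -> HaploidSet:
    """Split category-IV markers into double-cross categories IV and V.

    A co-dominant marker is category IV when the pattern on HapA matches
    the one on HapC (A with C, B with D) and category V when HapA's
    pattern matches HapD's (A with D, B with C).  Other categories are
    unchanged.
    """
    table = hs.table.copy()
    for m in table.index:
        if table.loc[m, "category"] != MarkerCategory.IV.name:
            continue
        pair = (table.loc[m, "hap_a"], table.loc[m, "hap_c"])
        table.loc[m, "updated_category"] = (
            MarkerCategory.IV.name if pair in (("A", "C"), ("B", "D")) else MarkerCategory.V.name
        )
    return HaploidSet(table=table)


_FEMALE_SWAP = {
    MarkerCategory.I: {"AC": "BC", "BC": "AC", "AD": "BD", "BD": "AD"},
    MarkerCategory.III: {"AX": "BX", "BX": "AX"},
    MarkerCategory.IV: {"AA": "BB", "BB": "AA"},
    MarkerCategory.V: {"AA": "BB", "BB": "AA"},
}
_MALE_SWAP = {
    MarkerCategory.I: {"AC": "AD", "AD": "AC", "BC": "BD", "BD": "BC"},
    MarkerCategory.II: {"XC": "XD", "XD": "XC"},
    # swapping C/D labels at a co-dominant locus does not change the
    # pattern-based genotype codes
}


def canonicalize_to_double_cross(
    gm: GenotypeMatrix,
    hs: HaploidSet,
) -> tuple[GenotypeMatrix, HaploidSet]:
    """Relabel alleles so HapA carries A and HapC carries C at every locus.

    Progeny genotype codes are relabelled consistently, category-IV
    markers take their updated IV/V category, and the population becomes a
    phase-known double cross.  Markers not in the haploid set keep their
    codes.  The operation is idempotent.
    """
    codes = gm.codes.copy()
    categories = dict(gm.categories)
    table = hs.table.copy()
    for m in hs.marker_ids:
        cat = gm.categories[m]
        new_cat = MarkerCategory[table.loc[m, "updated_category"]]
        categories[m] = new_cat
        if table.loc[m, "hap_a"] == "B":
            swap = _FEMALE_SWAP.get(cat, {})
            codes.loc[m] = [swap.get(g, g) for g in codes.loc[m]]
            table.loc[m, ["hap_a", "hap_b"]] = ["A", "B"]
        if table.loc[m, "hap_c"] == "D":
            swap = _MALE_SWAP.get(cat, {})
            codes.loc[m] = [swap.get(g, g) for g in codes.loc[m]]
            table.loc[m, ["hap_c", "hap_d"]] = ["C", "D"]
        table.loc[m, "category"] = new_cat.name
    new_gm = GenotypeMatrix(
        categories=categories,
        codes=codes,
        population=PopulationType.DOUBLE_CROSS,
    )
    return new_gm, HaploidSet(table=table)
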