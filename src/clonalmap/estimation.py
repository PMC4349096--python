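"""Maximum-likelihood estimation of recombination frequencies for marker pairs.

For every two-locus scenario the identifiable genotype classes have
theoretical frequencies that are polynomials in the female (``r_F``), male
(``r_M``), or combined (``r``) recombination frequency.  The log-likelihood
of observed class counts ``n_1..n_k`` is ``C + sum n_i log p_i``; MLEs come
from closed forms where the likelihood equation has an analytic root and
from Newton-Raphson iteration on the polynomial likelihood otherwise
(scenarios 4, 9 phases I/IV, and their double-cross analogues).

Linkage phase is the arrangement of alleles on each parent's homologues:

* phase I    - female coupling, male coupling
* phase II   - female coupling, male repulsion
* phase III  - female repulsion, male coupling
* phase IV   - female repulsion, male repulsion

A parental estimate above 0.5 signals repulsion; the combined estimate is
folded into [0, 0.5] through the phase-cased definitions so the combined
map never sees a repulsion artefact.  In the fully confounded scenario 9
(both loci co-dominant) the phase is chosen as the one whose likelihood
maximizes at the lowest ``r``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy.optimize import minimize_scalar

from .markers import (
    GenotypeMatrix,
    InvalidInputError,
    JointCounts,
    MarkerCategory,
    PopulationType,
    Scenario,
    classify_pair,
    joint_counts,
)

_EPS = 1e-9
LN10 = math.log(10.0)


class InestimableError(ValueError):
    """Raised when a pair carries no usable information (e.g. n = 0)."""


class Phase(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class PairEstimate:
    """Recombination-frequency estimates for one marker pair.

    ``r`` is the combined estimate, always in [0, 0.5].  ``r_f``/``r_m``
    are the parental estimates on their raw scale (a value above 0.5
    encodes repulsion phase and is what the haploid-building chain
    consumes); they are NaN when the scenario leaves that parent
    unobserved.  ``lod`` tests H0: r = 0.5 under the selected phase model.
    """

    scenario_id: int
    n: int
    r: float
    r_f: float
    r_m: float
    phase: Phase
    lod: float


# ---------------------------------------------------------------------------
# Class-frequency models (polynomials in one or two recombination parameters)
# ---------------------------------------------------------------------------

_R = Polynomial([0.0, 1.0])  # the identity polynomial r

# Substitutions turning the two-parameter models into one-parameter
# phase models for the combined r: (female argument, male argument).
_PHASE_SUBS: dict[Phase, tuple[Polynomial, Polynomial]] = {
    Phase.I: (_R, _R),
    Phase.II: (_R, 1 - _R),
    Phase.III: (1 - _R, _R),
    Phase.IV: (1 - _R, 1 - _R),
}

# Female/male recombinant indicator per class of the fully informative
# 16-class table (True where the frequency factor is r rather than 1-r).
_S1_FEMALE_REC = (False,) * 4 + (True,) * 8 + (False,) * 4
_S1_MALE_REC = tuple(i in {1, 2, 5, 6, 9, 10, 13, 14} for i in range(16))


def _model_s1(pf: Polynomial, pm: Polynomial) -> list[Polynomial]:
    return [
        0.25 * (pf if fr else 1 - pf) * (pm if mr else 1 - pm)
        for fr, mr in zip(_S1_FEMALE_REC, _S1_MALE_REC)
    ]


def _model_s2(pm: Polynomial) -> list[Polynomial]:
    q = 0.25 * (1 - pm)
    p = 0.25 * pm
    return [q, p, p, q, q, p, p, q]


def _model_s3(pf: Polynomial) -> list[Polynomial]:
    q = 0.25 * (1 - pf)
    p = 0.25 * pf
    return [q, p, q, p, p, q, p, q]


def _model_s4(pf: Polynomial, pm: Polynomial) -> list[Polynomial]:
    qf, qm = 1 - pf, 1 - pm
    return [
        0.25 * qf * qm,
        0.25 * (qf * pm + pf * qm),
        0.25 * pf * pm,
        0.25 * qf * pm,
        0.25 * (qf * qm + pf * pm),
        0.25 * pf * qm,
        0.25 * pf * qm,
        0.25 * (qf * qm + pf * pm),
        0.25 * qf * pm,
        0.25 * pf * pm,
        0.25 * (qf * pm + pf * qm),
        0.25 * qf * qm,
    ]


def _model_s5(pm: Polynomial) -> list[Polynomial]:
    q = 0.5 * (1 - pm)
    p = 0.5 * pm
    return [q, p, p, q]


def _model_s6(pm: Polynomial) -> list[Polynomial]:
    q = 0.25 * (1 - pm)
    p = 0.25 * pm
    quarter = Polynomial([0.25])
    return [q, quarter, p, p, quarter, q]


def _model_s9(pf: Polynomial, pm: Polynomial) -> list[Polynomial]:
    qf, qm = 1 - pf, 1 - pm
    hom = 0.25 * qf * qm          # both parents non-recombinant patterns
    het = 0.25 * (qf * pm + pf * qm)
    opp = 0.25 * pf * pm
    dbl = 0.5 * (qf * qm + pf * pm)
    return [hom, het, opp, het, dbl, het, opp, het, hom]


def phase_model(scenario_id: int, phase: Phase) -> list[Polynomial]:
    """Class probabilities as polynomials in the combined r for one phase."""
    pf, pm = _PHASE_SUBS[phase]
    if scenario_id == 1:
        return _model_s1(pf, pm)
    if scenario_id == 2:
        return _model_s2(pm)
    if scenario_id == 3:
        return _model_s3(pf)
    if scenario_id == 4:
        return _model_s4(pf, pm)
    if scenario_id == 5:
        return _model_s5(pm)
    if scenario_id == 6:
        return _model_s6(pm)
    if scenario_id == 7:
        return _model_s5(pf)
    if scenario_id == 8:
        return _model_s6(pf)
    if scenario_id == 9:
        return _model_s9(pf, pm)
    # Double-cross scenarios: category V relabels the male alleles, which
    # substitutes r_M -> 1 - r_M in the underlying clonal model.
    if scenario_id == 10:
        return _model_s4(pf, 1 - pm)
    if scenario_id == 11:
        return _model_s6(1 - pm)
    if scenario_id == 12:
        return _model_s6(pf)
    if scenario_id == 13:
        return _model_s9(pf, 1 - pm)
    if scenario_id == 14:
        return _model_s9(pf, pm)
    raise ValueError(f"unknown scenario id {scenario_id}")


# ---------------------------------------------------------------------------
# Likelihood maximization
# ---------------------------------------------------------------------------

def _loglik(counts: np.ndarray, model: list[Polynomial], r: float | np.ndarray):
    """Natural-log likelihood (up to the multinomial constant); 0*log(0)=0."""
    r = np.asarray(r, dtype=float)
    total = np.zeros_like(r)
    for c, p in zip(counts, model):
        if c > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                total = total + c * np.log(np.maximum(p(r), 0.0))
    return total


def maximize_loglik(
    counts: np.ndarray,
    model: list[Polynomial],
    lo: float = _EPS,
    hi: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> float:
    """Maximize the polynomial log-likelihood on [lo, hi].

    A coarse grid locates the global basin; Newton-Raphson with damped,
    clamped steps polishes the root of the score equation.  If Newton
    fails to improve, a bounded scalar search takes over.
    """
    grid = np.linspace(lo, hi, 401)
    ll_grid = _loglik(counts, model, grid)
    best = int(np.nanargmax(ll_grid))
    r = float(grid[best])
    ll_best = float(ll_grid[best])

    active = [(c, p, p.deriv(1), p.deriv(2)) for c, p in zip(counts, model) if c > 0]
    for _ in range(max_iter):
        d1 = d2 = 0.0
        for c, p, dp, ddp in active:
            v = p(r)
            if v <= 0:
                d1 = math.nan
                break
            g = dp(r) / v
            d1 += c * g
            d2 += c * (ddp(r) / v - g * g)
        if not math.isfinite(d1) or not math.isfinite(d2) or d2 >= 0:
            break
        step = d1 / d2
        r_new = min(max(r - step, lo), hi)
        # damp until the likelihood does not decrease
        for _ in range(30):
            if _loglik(counts, model, r_new) >= ll_best - 1e-12:
                break
            r_new = 0.5 * (r + r_new)
        if abs(r_new - r) < tol:
            r = r_new
            break
        ll_new = float(_loglik(counts, model, r_new))
        if ll_new < ll_best - 1e-9:
            break
        r, ll_best = r_new, ll_new

    if _loglik(counts, model, r) < ll_best - 1e-9:  # NR diverged; bounded search
        span = (grid[1] - grid[0]) * 2
        res = minimize_scalar(
            lambda x: -float(_loglik(counts, model, x)),
            bounds=(max(lo, grid[best] - span), min(hi, grid[best] + span)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        r = float(res.x)
    return float(min(max(r, lo), hi))


def _lod(counts: np.ndarray, model: list[Polynomial], r_hat: float) -> float:
    ll_alt = float(_loglik(counts, model, r_hat))
    ll_null = float(_loglik(counts, model, 0.5))
    return max((ll_alt - ll_null) / LN10, 0.0)


def _fold(r: float) -> float:
    return r if r <= 0.5 else 1.0 - r


# ---------------------------------------------------------------------------
# Per-scenario estimators
# ---------------------------------------------------------------------------

def _require_n(jc: JointCounts) -> np.ndarray:
    counts = jc.as_array()
    if counts.sum() <= 0:
        raise InestimableError("no progenies with both loci observed")
    return counts


def estimate_s1(jc: JointCounts) -> PairEstimate:
    """Fully informative pair: closed-form r_F, r_M; phase from their halves."""
    c = _require_n(jc)
    n = c.sum()
    r_f = float(np.compress(_S1_FEMALE_REC, c).sum() / n)
    r_m = float(np.compress(_S1_MALE_REC, c).sum() / n)
    if r_f <= 0.5 and r_m <= 0.5:
        phase, r = Phase.I, 0.5 * (r_f + r_m)
    elif r_f <= 0.5:
        phase, r = Phase.II, 0.5 * (r_f + 1.0 - r_m)
    elif r_m <= 0.5:
        phase, r = Phase.III, 0.5 * (1.0 - r_f + r_m)
    else:
        phase, r = Phase.IV, 1.0 - 0.5 * (r_f + r_m)
    lod = _lod(c, phase_model(1, phase), r)
    return PairEstimate(1, int(n), r, r_f, r_m, phase, lod)


def estimate_s2_s3(jc: JointCounts) -> PairEstimate:
    """One fully informative locus with a one-parent polymorphic partner."""
    c = _require_n(jc)
    n = c.sum()
    sid = jc.scenario.id
    if sid == 2:
        raw = float((c[1] + c[2] + c[5] + c[6]) / n)
        r_f, r_m = math.nan, raw
        model = _model_s2(_R)
        phase = Phase.I if raw <= 0.5 else Phase.II
    else:
        raw = float((c[1] + c[3] + c[4] + c[6]) / n)
        r_f, r_m = raw, math.nan
        model = _model_s3(_R)
        phase = Phase.I if raw <= 0.5 else Phase.III
    lod = _lod(c, model, raw)
    return PairEstimate(sid, int(n), _fold(raw), r_f, r_m, phase, lod)


def estimate_s4(jc: JointCounts) -> PairEstimate:
    """Fully informative x co-dominant pair.

    r_F and r_M come from the half of the classes where locus 2 is
    homozygous (the heterozygote confounds the parents); the phase they
    imply selects the 12-class likelihood that Newton-Raphson maximizes
    for the combined r.
    """
    c = _require_n(jc)
    n = c.sum()
    informative = c[[0, 2, 3, 5, 6, 8, 9, 11]].sum()
    if informative > 0:
        r_f = float((c[2] + c[5] + c[6] + c[9]) / informative)
        r_m = float((c[2] + c[3] + c[8] + c[9]) / informative)
        if r_f <= 0.5 and r_m <= 0.5:
            phase = Phase.I
        elif r_f <= 0.5:
            phase = Phase.II
        elif r_m <= 0.5:
            phase = Phase.III
        else:
            phase = Phase.IV
        model = phase_model(4, phase)
        r = maximize_loglik(c, model)
    else:
        # no homozygous classes observed: search all four phase likelihoods
        # and keep the lowest estimate, mirroring the scenario-9 logic
        fits = {}
        for ph in (Phase.I, Phase.II, Phase.III, Phase.IV):
            fits[ph] = maximize_loglik(c, phase_model(4, ph))
        phase = min(fits, key=lambda ph: (fits[ph], ph.value))
        r = fits[phase]
        model = phase_model(4, phase)
        r_f = r if phase in (Phase.I, Phase.II) else 1.0 - r
        r_m = r if phase in (Phase.I, Phase.III) else 1.0 - r
    lod = _lod(c, model, r)
    return PairEstimate(4, int(n), r, r_f, r_m, phase, lod)


def estimate_s5_s7(jc: JointCounts) -> PairEstimate:
    """Both loci polymorphic in the same single parent (2x2 classes)."""
    c = _require_n(jc)
    n = c.sum()
    raw = float((c[1] + c[2]) / n)
    sid = jc.scenario.id
    if sid == 5:
        r_f, r_m = math.nan, raw
        phase = Phase.I if raw <= 0.5 else Phase.II
    else:
        r_f, r_m = raw, math.nan
        phase = Phase.I if raw <= 0.5 else Phase.III
    lod = _lod(c, _model_s5(_R), raw)
    return PairEstimate(sid, int(n), _fold(raw), r_f, r_m, phase, lod)


def estimate_s6_s8(jc: JointCounts) -> PairEstimate:
    """One-parent polymorphic locus x co-dominant locus.

    The double-heterozygote classes (frequency 1/4 regardless of r) are
    uninformative and drop out of the estimator.
    """
    c = _require_n(jc)
    n = c.sum()
    denom = c[0] + c[2] + c[3] + c[5]
    if denom <= 0:
        raise InestimableError("only uninformative heterozygote classes observed")
    raw = float((c[2] + c[3]) / denom)
    sid = jc.scenario.id
    if sid == 6:
        r_f, r_m = math.nan, raw
        phase = Phase.I if raw <= 0.5 else Phase.II
    else:
        r_f, r_m = raw, math.nan
        phase = Phase.I if raw <= 0.5 else Phase.III
    lod = _lod(c, _model_s6(_R), raw)
    return PairEstimate(sid, int(n), _fold(raw), r_f, r_m, phase, lod)


def closed_form_s9_phase23(counts: np.ndarray) -> float:
    """Closed-form MLE of r under the scenario-9 phase-II/III model.

    r = (1 - sqrt(1 - 2s))/2 with s the frequency of the corner and
    double-heterozygote classes; when the square-root argument is
    negative the MLE sits at the boundary r = 0.5.
    """
    n = counts.sum()
    s = (counts[0] + counts[2] + counts[4] + counts[6] + counts[8]) / n
    arg = 1.0 - 2.0 * s
    if arg <= 0:
        return 0.5
    return 0.5 * (1.0 - math.sqrt(arg))


def s9_phase_estimates(counts: np.ndarray) -> dict[Phase, float]:
    """MLE of r under each of the four phase models of scenario 9.

    Each phase likelihood is maximized over (0, 1); a mismatched phase
    peaks at 1 - r_true, the matched one at r_true.  The phase-IV model is
    the phase-I model mirrored at r -> 1 - r, so its maximizer is the
    mirror of the phase-I maximizer.
    """
    r1 = maximize_loglik(counts, _model_s9(_R, _R), lo=_EPS, hi=1.0 - _EPS)
    r23 = closed_form_s9_phase23(counts)
    return {Phase.I: r1, Phase.II: r23, Phase.III: r23, Phase.IV: 1.0 - r1}


def estimate_s9(jc: JointCounts) -> PairEstimate:
    """Co-dominant x co-dominant pair: phase and r estimated jointly.

    The phase whose likelihood maximizes at the lowest r is taken as true;
    r_F and r_M are then the phase-implied values (r for a coupling
    parent, 1-r for a repulsion parent).  The II/III ambiguity (the two
    are genetically equivalent) is resolved deterministically to II; a
    tie at 0.5 leaves the phase unassigned.
    """
    c = _require_n(jc)
    n = c.sum()
    fits = s9_phase_estimates(c)
    order = (Phase.I, Phase.II, Phase.IV)  # III equivalent to II
    phase = min(order, key=lambda ph: fits[ph])
    r = fits[phase]
    if r >= 0.5 - 1e-12:
        phase_out = Phase.UNASSIGNED
        r = 0.5
        r_f = r_m = 0.5
        model = _model_s9(_R, _R)
    else:
        phase_out = phase
        r_f = r if phase in (Phase.I, Phase.II) else 1.0 - r
        r_m = r if phase in (Phase.I, Phase.III) else 1.0 - r
        model = phase_model(9, phase)
    lod = _lod(c, model, r)
    return PairEstimate(9, int(n), r, r_f, r_m, phase_out, lod)


def estimate_double_cross(jc: JointCounts) -> PairEstimate:
    """Scenarios 10-14: pairs involving category V in a phase-known double cross.

    Phases are known (both F1 parents in coupling), so no phase search is
    performed; the category-V relabelling enters the model as the
    r_M -> 1 - r_M substitution.
    """
    c = _require_n(jc)
    n = c.sum()
    sid = jc.scenario.id
    if sid == 10:
        informative = c[[0, 2, 3, 5, 6, 8, 9, 11]].sum()
        if informative > 0:
            r_f = float((c[2] + c[5] + c[6] + c[9]) / informative)
            # Eq-8 on the substituted model estimates 1 - r_M
            r_m = 1.0 - float((c[2] + c[3] + c[8] + c[9]) / informative)
        else:
            r_f = r_m = math.nan
        model = phase_model(10, Phase.I)
        r = maximize_loglik(c, model)
        if informative <= 0:
            r_f = r_m = r
    elif sid == 11:
        denom = c[0] + c[2] + c[3] + c[5]
        if denom <= 0:
            raise InestimableError("only uninformative heterozygote classes observed")
        r_m = float((c[0] + c[5]) / denom)
        r_f = math.nan
        model = phase_model(11, Phase.I)
        r, raw = _fold(r_m), r_m
    elif sid == 12:
        denom = c[0] + c[2] + c[3] + c[5]
        if denom <= 0:
            raise InestimableError("only uninformative heterozygote classes observed")
        r_f = float((c[2] + c[3]) / denom)
        r_m = math.nan
        model = phase_model(12, Phase.I)
        r, raw = _fold(r_f), r_f
    elif sid == 13:
        r = closed_form_s9_phase23(c)
        r_f = r_m = r
        model = phase_model(13, Phase.I)
    elif sid == 14:
        model = phase_model(14, Phase.I)
        r = maximize_loglik(c, model)
        r_f = r_m = r
    else:
        raise ValueError(f"not a double-cross scenario: {sid}")
    # the LOD evaluates the likelihood at the raw (unfolded) MLE
    lod = _lod(c, model, raw if sid in (11, 12) else r)
    return PairEstimate(sid, int(n), min(r, 0.5), r_f, r_m, Phase.I, lod)


_ESTIMATORS = {
    1: estimate_s1,
    2: estimate_s2_s3,
    3: estimate_s2_s3,
    4: estimate_s4,
    5: estimate_s5_s7,
    6: estimate_s6_s8,
    7: estimate_s5_s7,
    8: estimate_s6_s8,
    9: estimate_s9,
    10: estimate_double_cross,
    11: estimate_double_cross,
    12: estimate_double_cross,
    13: estimate_double_cross,
    14: estimate_double_cross,
}


def estimate_pair(jc: JointCounts) -> PairEstimate:
    """Dispatch a tabulated marker pair to its scenario estimator."""
    if jc.scenario.id is None:
        raise InestimableError("II-III pairs carry no linkage information")
    return _ESTIMATORS[jc.scenario.id](jc)


# ---------------------------------------------------------------------------
# All-pairs estimation
# ---------------------------------------------------------------------------

@dataclass
class RecombMatrix:
    """Symmetric pairwise matrices of estimates for a genotype matrix.

    ``r_f``/``r_m`` hold the raw parental values (possibly above 0.5,
    encoding repulsion).  ``mask`` is True where the combined r could be
    estimated; II-III pairs and degenerate pairs are False.
    """

    marker_ids: list[str]
    categories: dict[str, MarkerCategory]
    r: pd.DataFrame
    r_f: pd.DataFrame
    r_m: pd.DataFrame
    lod: pd.DataFrame
    mask: pd.DataFrame
    scenario_ids: pd.DataFrame
    phases: pd.DataFrame

    def category(self, marker: str) -> MarkerCategory:
        return self.categories[marker]


def estimate_all_pairs(gm: GenotypeMatrix) -> RecombMatrix:
    """Estimate r, r_F, r_M and LOD for every marker pair of a population."""
    ids = gm.marker_ids
    m = len(ids)
    nan = np.full((m, m), np.nan)
    r = pd.DataFrame(nan.copy(), index=ids, columns=ids)
    r_f = pd.DataFrame(nan.copy(), index=ids, columns=ids)
    r_m = pd.DataFrame(nan.copy(), index=ids, columns=ids)
    lod = pd.DataFrame(nan.copy(), index=ids, columns=ids)
    mask = pd.DataFrame(np.zeros((m, m), dtype=bool), index=ids, columns=ids)
    sids = pd.DataFrame(np.zeros((m, m), dtype=int), index=ids, columns=ids)
    phases = pd.DataFrame(np.full((m, m), "", dtype=object), index=ids, columns=ids)

    cols = {mk: list(gm.codes.loc[mk]) for mk in ids}
    for a, b in combinations(ids, 2):
        scen = classify_pair(gm.categories[a], gm.categories[b], gm.population)
        if scen.id is None:
            continue
        try:
            est = estimate_pair(joint_counts(cols[a], cols[b], scen))
        except InestimableError:
            continue
        for df, val in (
            (r, est.r), (r_f, est.r_f), (r_m, est.r_m), (lod, est.lod),
        ):
            df.loc[a, b] = val
            df.loc[b, a] = val
        mask.loc[a, b] = mask.loc[b, a] = True
        sids.loc[a, b] = sids.loc[b, a] = est.scenario_id
        phases.loc[a, b] = phases.loc[b, a] = est.phase.value
    return RecombMatrix(
        marker_ids=ids,
        categories=dict(gm.categories),
        r=r, r_f=r_f, r_m=r_m, lod=lod, mask=mask,
        scenario_ids=sids, phases=phases,
    )
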