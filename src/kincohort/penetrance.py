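"""Marginal-likelihood kin-cohort estimation of age-specific penetrance.

Each first-degree relative contributes follow-up (t_i, delta_i) for one
outcome and a mixing weight p_i = P(carrier | proband genotype, relation,
observed genotype).  With nonparametric discrete-time hazards
lambda_g(t_k) on the grid of distinct event ages, the per-woman likelihood
is the two-class genotype mixture

    L_i = p_i L_1(t_i, d_i) + (1 - p_i) L_0(t_i, d_i),
    L_g(t, d) = lambda_g(t)^d * prod_{t_k < t} (1 - lambda_g(t_k))
                * (1 - lambda_g(t))^{(1-d) [t in grid]},

and the hazards are fitted by EM: the E-step computes each woman's
posterior carrier probability pi_i given her full follow-up, the M-step is
a pi-weighted occurrence/exposure (actuarial) update on each grid age.
Cumulative penetrance is F(t) = 1 - prod_{origin < t_k <= t}(1 - lambda(t_k)),
and confidence bands come from a nonparametric bootstrap that resamples
whole families (the clustering unit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .mendelian import GenotypeModel, MixingWeight, mixing_weight
from .records import Family, FollowUpRecord, ValidationError, derive_followup
from .tables import NEGATIVE_STATUS

__all__ = [
    "HazardTable",
    "EMState",
    "EstimatorConfig",
    "PenetranceCurve",
    "PenetranceResult",
    "marginal_loglik",
    "fit_mml_em",
    "cumulative_risk",
    "bootstrap_ci",
]

logger = logging.getLogger(__name__)

#: reporting start age per outcome (penetrance accrues from this age)
DEFAULT_ORIGIN = {"breast": 20.0, "ovarian": 30.0}
#: ages at which cumulative risk is tabulated per outcome
DEFAULT_REPORT_AGES = {"breast": (40.0, 50.0, 60.0, 70.0),
                       "ovarian": (50.0, 60.0, 70.0)}


@dataclass
class HazardTable:
    """Discrete-time hazards for the carrier and noncarrier classes on a
    strictly increasing age grid (the distinct observed event ages)."""

    grid: np.ndarray
    lambda_carrier: np.ndarray
    lambda_noncarrier: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.lambda_carrier = np.asarray(self.lambda_carrier, dtype=float)
        self.lambda_noncarrier = np.asarray(self.lambda_noncarrier, dtype=float)
        if not (len(self.grid) == len(self.lambda_carrier)
                == len(self.lambda_noncarrier)):
            raise ValueError("grid and hazard vectors must share a length")
        if len(self.grid) > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        for name, lam in (("lambda_carrier", self.lambda_carrier),
                          ("lambda_noncarrier", self.lambda_noncarrier)):
            if np.any((lam < 0) | (lam > 1)):
                raise ValueError(f"{name} outside [0, 1]")

    def hazard(self, group: str) -> np.ndarray:
        if group == "carrier":
            return self.lambda_carrier
        if group == "noncarrier":
            return self.lambda_noncarrier
        raise ValueError(f"unknown group {group!r}")


@dataclass
class EMState:
    """Result of one EM fit."""

    hazards: HazardTable
    posterior: np.ndarray  # per analysed relative, in input order
    loglik: float
    n_iter: int
    converged: bool
    n_events: float = 0.0
    n_relatives: int = 0
    loglik_trace: list = field(default_factory=list)


@dataclass
class EstimatorConfig:
    """Tunables for the EM fit and the family bootstrap."""

    tol: float = 1e-8
    boot_tol: float = 1e-6
    max_iter: int = 5000
    B: int = 1000
    seed: Optional[int] = None
    age_origin: Optional[float] = None
    report_ages: Optional[Sequence[float]] = None
    min_events_for_ci: int = 10
    mendelian_method: str = "exact"

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.boot_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    def origin_for(self, outcome: str) -> float:
        return (self.age_origin if self.age_origin is not None
                else DEFAULT_ORIGIN[outcome])

    def report_ages_for(self, outcome: str) -> np.ndarray:
        ages = (self.report_ages if self.report_ages is not None
                else DEFAULT_REPORT_AGES[outcome])
        return np.asarray(ages, dtype=float)


@dataclass
class PenetranceCurve:
    """Cumulative risk F(t) at a set of ages, with optional bootstrap band."""

    ages: np.ndarray
    F: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if np.any((self.F < -1e-12) | (self.F > 1 + 1e-12)):
            raise ValueError("F outside [0, 1]")
        if np.any(np.diff(self.F) < -1e-12):
            raise ValueError("F must be nondecreasing")


@dataclass
class PenetranceResult:
    """Point estimates plus bootstrap bands for both genotype classes."""

    gene: str
    outcome: str
    carrier: PenetranceCurve
    noncarrier: PenetranceCurve
    state: EMState
    q: float
    B: int = 0
    seed: Optional[int] = None
    n_zero_event_replicates: int = 0


# ---------------------------------------------------------------------------
# array plumbing

@dataclass
class _AnalysisArrays:
    t: np.ndarray
    d: np.ndarray
    p: np.ndarray
    fam_index: np.ndarray
    person_ids: list
    n_families: int


def _build_arrays(families: Sequence[Family], outcome: str,
                  model: GenotypeModel, method: str) -> _AnalysisArrays:
    """Follow-up and mixing-weight arrays for the relatives of all families
    usable in this gene's analysis (gene-positive plus mutation-negative)."""
    t, d, p, fam_index, person_ids = [], [], [], [], []
    n_fam = 0
    n_skipped_other_gene = 0
    # cache the two Mendelian priors per relation
    prior: dict[tuple[str, str], float] = {}
    for fam in families:
        status = fam.proband_gene_status
        if status == model.gene:
            pro = "carrier"
        elif status == NEGATIVE_STATUS:
            pro = "noncarrier"
        else:
            n_skipped_other_gene += 1
            continue
        idx = n_fam
        n_fam += 1
        for rel in fam.relatives:
            try:
                fu = derive_followup(rel, outcome)
            except ValidationError:
                continue
            if rel.genotype == "carrier":
                w = 1.0
            elif rel.genotype == "noncarrier":
                w = 0.0
            else:
                key = (pro, rel.role)
                if key not in prior:
                    prior[key] = mixing_weight(rel, pro, model, method).p
                w = prior[key]
            t.append(fu.time)
            d.append(fu.event)
            p.append(w)
            fam_index.append(idx)
            person_ids.append(rel.person_id)
    if n_skipped_other_gene:
        logger.info("skipped %d families positive for a different gene",
                    n_skipped_other_gene)
    return _AnalysisArrays(np.asarray(t, dtype=float),
                           np.asarray(d, dtype=np.int64),
                           np.asarray(p, dtype=float),
                           np.asarray(fam_index, dtype=np.int64),
                           person_ids, n_fam)


def _grid_positions(grid: np.ndarray, t: np.ndarray):
    """Positions of each follow-up time relative to the grid.

    Returns (j, a, r): j = number of grid ages strictly below t;
    a = index of t in the grid, or -1; r = number of grid ages <= t.
    """
    j = np.searchsorted(grid, t, side="left")
    in_grid = (j < len(grid)) & (grid[np.minimum(j, len(grid) - 1)] == t)
    a = np.where(in_grid, j, -1)
    r = j + in_grid
    return j, a, r


def _class_loglik(lam: np.ndarray, j: np.ndarray, a: np.ndarray,
                  d: np.ndarray) -> np.ndarray:
    """log L_g(t_i, d_i) for every row under one class's hazards."""
    with np.errstate(divide="ignore"):
        c = np.log1p(-lam)          # log(1 - lambda); -inf at lambda = 1
        loglam = np.log(lam)        # -inf at lambda = 0
    cums = np.concatenate(([0.0], np.cumsum(c)))
    ll = cums[j]
    own = a >= 0
    ak = a[own]
    ll_own = np.where(d[own] == 1, loglam[ak], c[ak])
    out = ll.copy()
    out[own] = out[own] + ll_own
    return out


def _mixture(p, l1, l0):
    """Row posteriors and log-likelihood contributions, computed stably."""
    m = np.maximum(l1, l0)
    bad = ~np.isfinite(m)
    m_safe = np.where(bad, 0.0, m)
    e1 = p * np.exp(l1 - m_safe)
    e0 = (1.0 - p) * np.exp(l0 - m_safe)
    tot = e1 + e0
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(tot > 0, e1 / np.where(tot > 0, tot, 1.0), p)
        ll = m_safe + np.log(tot)
    ll[bad] = -np.inf
    pi[bad] = p[bad]
    return pi, ll


def _mstep(pi, w, d, a, r, K):
    """pi-weighted occurrence/exposure hazard update for one class."""
    ev = d == 1
    wpi = w * pi
    num = np.bincount(a[ev], weights=wpi[ev], minlength=K)
    cnt = np.bincount(r, weights=wpi, minlength=K + 1)
    S = np.cumsum(cnt)
    den = S[-1] - S[:K]  # mass with r >= k+1, i.e. t_i >= grid[k]
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(lam, 0.0, 1.0)


def _wsum(w, ll_rows):
    """Weighted sum that ignores zero-weight rows (whose log-likelihood may
    be -inf when a bootstrap resample drops them entirely)."""
    live = w > 0
    return float(np.dot(w[live], ll_rows[live]))


def _fit_arrays(t, d, p, w, grid, tol, max_iter, init=None):
    """EM over aggregated rows; returns (lam1, lam0, pi, loglik, iters,
    converged, loglik_trace)."""
    K = len(grid)
    j, a, r = _grid_positions(grid, t)
    if np.any((d == 1) & (a < 0)):
        raise ValueError("event age absent from hazard grid")
    if init is None:
        pooled = _mstep(np.ones_like(p), w, d, a, r, K)
        lam1 = pooled.copy()
        lam0 = pooled.copy()
    else:
        lam1, lam0 = init[0].copy(), init[1].copy()
    prev = -np.inf
    pi = p.copy()
    converged = False
    it = 0
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        l1 = _class_loglik(lam1, j, a, d)
        l0 = _class_loglik(lam0, j, a, d)
        pi, ll_rows = _mixture(p, l1, l0)
        loglik = _wsum(w, ll_rows)
        trace.append(loglik)
        lam1 = _mstep(pi, w, d, a, r, K)
        lam0 = _mstep(1.0 - pi, w, d, a, r, K)
        if np.isfinite(loglik) and loglik - prev < tol and it > 1:
            converged = True
            break
        prev = loglik
    # loglik of the returned hazards (one M-step past the last E-step)
    l1 = _class_loglik(lam1, j, a, d)
    l0 = _class_loglik(lam0, j, a, d)
    pi, ll_rows = _mixture(p, l1, l0)
    final = _wsum(w, ll_rows)
    trace.append(final)
    return lam1, lam0, pi, final, it, converged, trace


def _fit_arrays_batch(t, d, p, W, grid, tol, max_iter, init):
    """EM run simultaneously over the rows of a replicate-weight matrix.

    ``W`` has one row of aggregated-pattern weights per bootstrap
    replicate; every replicate shares the (t, d, p) patterns and the grid,
    so the E- and M-steps vectorize across replicates (the M-step becomes
    two matmuls against event- and risk-set indicator matrices).  Returns
    hazard matrices of shape (B, K).  Iteration stops when every
    replicate's log-likelihood improvement falls below ``tol``.
    """
    B = W.shape[0]
    K = len(grid)
    j, a, r = _grid_positions(grid, t)
    if np.any((d == 1) & (a < 0)):
        raise ValueError("event age absent from hazard grid")
    own = np.flatnonzero(a >= 0)
    ak = a[own]
    d_own_event = d[own] == 1
    # indicator matrices: events at each grid age / membership in each risk set
    U = len(t)
    E = np.zeros((U, K))
    ev = np.flatnonzero(d == 1)
    E[ev, a[ev]] = 1.0
    R = (r[:, None] >= np.arange(1, K + 1)[None, :]).astype(float)

    lam1 = np.tile(init[0], (B, 1))
    lam0 = np.tile(init[1], (B, 1))
    prev = np.full(B, -np.inf)
    live = W > 0
    out1 = np.empty((B, K))
    out0 = np.empty((B, K))
    idx = np.arange(B)  # original replicate id of each active row

    def class_ll(lam):
        with np.errstate(divide="ignore"):
            c = np.log1p(-lam)
            loglam = np.log(lam)
        cums = np.concatenate([np.zeros((lam.shape[0], 1)),
                               np.cumsum(c, axis=1)], axis=1)
        ll = cums[:, j]
        ll[:, own] += np.where(d_own_event[None, :], loglam[:, ak], c[:, ak])
        return ll

    for it in range(1, max_iter + 1):
        l1 = class_ll(lam1)
        l0 = class_ll(lam0)
        m = np.maximum(l1, l0)
        bad = ~np.isfinite(m)
        m_safe = np.where(bad, 0.0, m)
        e1 = p[None, :] * np.exp(l1 - m_safe)
        e0 = (1.0 - p[None, :]) * np.exp(l0 - m_safe)
        tot = e1 + e0
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(tot > 0, e1 / np.where(tot > 0, tot, 1.0),
                          p[None, :])
            ll_rows = m_safe + np.log(tot)
        ll_rows[bad] = -np.inf
        with np.errstate(invalid="ignore"):
            loglik = np.sum(np.where(live, W * ll_rows, 0.0), axis=1)
        wp1 = W * pi
        wp0 = W - wp1
        num1, den1 = wp1 @ E, wp1 @ R
        num0, den0 = wp0 @ E, wp0 @ R
        with np.errstate(invalid="ignore", divide="ignore"):
            lam1 = np.clip(np.where(den1 > 0,
                                    num1 / np.where(den1 > 0, den1, 1.0),
                                    0.0), 0.0, 1.0)
            lam0 = np.clip(np.where(den0 > 0,
                                    num0 / np.where(den0 > 0, den0, 1.0),
                                    0.0), 0.0, 1.0)
        conv = np.isfinite(loglik) & (loglik - prev < tol) & (it > 1)
        prev = loglik
        if np.any(conv):
            out1[idx[conv]] = lam1[conv]
            out0[idx[conv]] = lam0[conv]
            keep = ~conv
            idx = idx[keep]
            if idx.size == 0:
                break
            lam1, lam0 = lam1[keep], lam0[keep]
            W, prev, live = W[keep], prev[keep], live[keep]
    if idx.size:  # ran out of iterations for some replicates
        out1[idx] = lam1
        out0[idx] = lam0
    return out1, out0


def _aggregate(t, d, p):
    """Collapse identical (t, d, p) rows; returns unique arrays, an inverse
    map, and base counts.  The EM cost then scales with the number of
    distinct patterns rather than the number of relatives."""
    stacked = np.column_stack([t, d.astype(float), p])
    uniq, inverse = np.unique(stacked, axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=len(uniq)).astype(float)
    return (uniq[:, 0], uniq[:, 1].astype(np.int64), uniq[:, 2],
            inverse, counts)


# ---------------------------------------------------------------------------
# public operations

def marginal_loglik(followups: Iterable[FollowUpRecord],
                    weights: Iterable[MixingWeight],
                    hazards: HazardTable) -> float:
    """Marginal log-likelihood of follow-up records under a hazard table.

    Sums log[p_i L_1 + (1 - p_i) L_0] over records; raises if an event age
    is missing from the hazard grid.
    """
    fu = list(followups)
    ws = list(weights)
    if len(fu) != len(ws):
        raise ValueError("one mixing weight per follow-up record required")
    t = np.asarray([f.time for f in fu], dtype=float)
    d = np.asarray([f.event for f in fu], dtype=np.int64)
    p = np.asarray([w.p for w in ws], dtype=float)
    grid = hazards.grid
    j, a, r = _grid_positions(grid, t)
    if np.any((d == 1) & (a < 0)):
        raise ValueError("event age absent from hazard grid")
    l1 = _class_loglik(hazards.lambda_carrier, j, a, d)
    l0 = _class_loglik(hazards.lambda_noncarrier, j, a, d)
    _, ll_rows = _mixture(p, l1, l0)
    return float(np.sum(ll_rows))


def fit_mml_em(families: Sequence[Family], outcome: str,
               model: GenotypeModel,
               config: Optional[EstimatorConfig] = None) -> EMState:
    """Fit genotype-specific discrete hazards by EM on all usable relatives.

    The analysis set is the gene-positive families (carrier probands)
    plus the mutation-negative families (noncarrier probands); families
    positive for a different gene are skipped.
    """
    config = config or EstimatorConfig()
    arrays = _build_arrays(families, outcome, model, config.mendelian_method)
    if arrays.t.size == 0:
        raise ValueError("no usable relatives for this outcome")
    if arrays.d.sum() == 0:
        raise ValueError("no events for this outcome: hazards inestimable")
    grid = np.unique(arrays.t[arrays.d == 1])
    tu, du, pu, inverse, w = _aggregate(arrays.t, arrays.d, arrays.p)
    lam1, lam0, pi_u, ll, it, conv, trace = _fit_arrays(
        tu, du, pu, w, grid, config.tol, config.max_iter)
    if not conv:
        logger.warning("EM did not converge in %d iterations "
                       "(last loglik %.6f)", it, ll)
    hazards = HazardTable(grid, lam1, lam0)
    posterior = pi_u[inverse]
    return EMState(hazards=hazards, posterior=posterior, loglik=ll,
                   n_iter=it, converged=conv,
                   n_events=float(arrays.d.sum()),
                   n_relatives=int(arrays.t.size),
                   loglik_trace=trace)


def _cumrisk_values(grid, lam, from_age, ages):
    """F at each requested age, accruing hazard on grid ages in
    (from_age, age]."""
    mask = grid > from_age
    g = grid[mask]
    surv = np.cumprod(1.0 - lam[mask])
    idx = np.searchsorted(g, np.asarray(ages, dtype=float), side="right")
    S = np.concatenate(([1.0], surv))[idx]
    return 1.0 - S


def cumulative_risk(hazards: HazardTable, from_age: float, to_age: float,
                    group: str = "carrier",
                    ages: Optional[Sequence[float]] = None) -> PenetranceCurve:
    """Cumulative penetrance F(t) = 1 - prod_{from_age < t_k <= t}(1 - lambda).

    ``ages`` defaults to every grid age inside (from_age, to_age] plus
    ``to_age`` itself.
    """
    if from_age >= to_age:
        raise ValueError("from_age must precede to_age")
    lam = hazards.hazard(group)
    if ages is None:
        inside = hazards.grid[(hazards.grid > from_age)
                              & (hazards.grid <= to_age)]
        ages = np.unique(np.concatenate([inside, [to_age]]))
    F = _cumrisk_values(hazards.grid, lam, from_age, ages)
    return PenetranceCurve(ages=np.asarray(ages, dtype=float), F=F)


def bootstrap_ci(families: Sequence[Family], outcome: str,
                 model: GenotypeModel,
                 config: Optional[EstimatorConfig] = None) -> PenetranceResult:
    """Point estimate plus family-bootstrap percentile confidence band.

    Families (the clustering unit) are resampled with replacement B times;
    each replicate refits the EM (warm-started at the point estimate) and
    evaluates F at the report ages.  Replicates with no events contribute
    F = 0.  A genotype class with fewer than ``min_events_for_ci``
    (posterior-weighted) events is reported without a band, since so few
    cases do not permit reasonable interval estimation.
    """
    config = config or EstimatorConfig()
    origin = config.origin_for(outcome)
    report = config.report_ages_for(outcome)

    arrays = _build_arrays(families, outcome, model, config.mendelian_method)
    if arrays.t.size == 0 or arrays.d.sum() == 0:
        raise ValueError("no events for this outcome: hazards inestimable")
    grid = np.unique(arrays.t[arrays.d == 1])
    tu, du, pu, inverse, base_w = _aggregate(arrays.t, arrays.d, arrays.p)
    lam1, lam0, pi_u, ll, it, conv, trace = _fit_arrays(
        tu, du, pu, base_w, grid, config.tol, config.max_iter)
    if not conv:
        logger.warning("EM did not converge in %d iterations", it)
    hazards = HazardTable(grid, lam1, lam0)
    state = EMState(hazards=hazards, posterior=pi_u[inverse], loglik=ll,
                    n_iter=it, converged=conv,
                    n_events=float(arrays.d.sum()),
                    n_relatives=int(arrays.t.size),
                    loglik_trace=trace)

    F1 = _cumrisk_values(grid, lam1, origin, report)
    F0 = _cumrisk_values(grid, lam0, origin, report)
    if np.any(F1 + 1e-9 < F0):
        logger.warning("carrier and noncarrier penetrance curves cross")

    ev1 = float(np.sum(base_w * pi_u * du))
    ev0 = float(np.sum(base_w * (1.0 - pi_u) * du))
    want_ci = {"carrier": ev1 >= config.min_events_for_ci,
               "noncarrier": ev0 >= config.min_events_for_ci}
    for group, ok in want_ci.items():
        if not ok:
            logger.warning("%s class has too few events (%.1f) for a "
                           "confidence band", group,
                           ev1 if group == "carrier" else ev0)

    rng = np.random.default_rng(config.seed)
    n_fam = arrays.n_families
    boot1 = np.zeros((config.B, len(report)))
    boot0 = np.zeros((config.B, len(report)))
    W = np.empty((config.B, len(tu)))
    for b in range(config.B):
        draws = rng.integers(0, n_fam, n_fam)
        fam_counts = np.bincount(draws, minlength=n_fam)
        row_w = fam_counts[arrays.fam_index].astype(float)
        W[b] = np.bincount(inverse, weights=row_w, minlength=len(tu))
    has_events = (W @ du.astype(float)) > 0
    n_zero = int(np.sum(~has_events))
    if np.any(has_events):
        bl1, bl0 = _fit_arrays_batch(tu, du, pu, W[has_events], grid,
                                     config.boot_tol, config.max_iter,
                                     init=(lam1, lam0))
        mask = grid > origin
        g = grid[mask]
        idx = np.searchsorted(g, report, side="right")
        for lam_mat, out in ((bl1, boot1), (bl0, boot0)):
            surv = np.concatenate(
                [np.ones((lam_mat.shape[0], 1)),
                 np.cumprod(1.0 - lam_mat[:, mask], axis=1)], axis=1)
            out[has_events] = 1.0 - surv[:, idx]
    if n_zero:
        logger.warning("%d bootstrap replicates had no events "
                       "(recorded as F = 0)", n_zero)

    def _curve(F, boot, ok):
        if ok:
            lo = np.percentile(boot, 2.5, axis=0)
            hi = np.percentile(boot, 97.5, axis=0)
            # percentile bands can sit slightly off the point estimate in
            # tiny samples; clip so the band always brackets it
            lo = np.minimum(lo, F)
            hi = np.maximum(hi, F)
        else:
            lo = hi = None
        return PenetranceCurve(ages=report, F=F, ci_low=lo, ci_high=hi)

    return PenetranceResult(
        gene=model.gene, outcome=outcome,
        carrier=_curve(F1, boot1, want_ci["carrier"]),
        noncarrier=_curve(F0, boot0, want_ci["noncarrier"]),
        state=state, q=model.q, B=config.B, seed=config.seed,
        n_zero_event_replicates=n_zero)
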