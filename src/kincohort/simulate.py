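"""Synthetic kin-cohort registry generator with known truth.

Emulates a hereditary breast/ovarian cancer family registry: families are
ascertained through an affected, genotyped proband; each family
contributes the proband's mother plus a random number of sisters and
daughters; founder genotypes follow Hardy-Weinberg equilibrium and alleles
are transmitted by Mendel's laws; each woman's breast and ovarian onset
ages are drawn from genotype-specific discrete yearly hazards; follow-up
ends at a role-specific last-contact age, with occasional risk-reducing
surgeries; and only a fraction gamma of relatives is genotyped.

The generator returns regular :class:`~kincohort.records.Family` objects
plus a truth sidecar (true genotypes and the true hazard schedules), so
every estimator property can be checked against known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .mendelian import hwe_genotype_freqs
from .penetrance import HazardTable
from .records import Family, IndividualRecord
from .tables import NEGATIVE_STATUS

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationError",
    "hazards_from_anchors",
    "simulate_families",
    "mask_genotypes",
]


class SimulationError(RuntimeError):
    """Simulation cannot proceed (e.g. ascertainment never succeeds)."""


def hazards_from_anchors(anchors: Sequence[tuple[float, float]],
                         max_age: int = 90) -> np.ndarray:
    """Yearly hazards on ages 1..max_age matching cumulative-risk anchors.

    ``anchors`` is a list of (age, F) pairs with F the cumulative risk from
    birth; the hazard is constant within each band and solves
    1 - F(b) = (1 - F(a)) * (1 - lam)^(b - a).  The hazard is zero before
    the first anchor and holds the last band's value beyond the last.
    """
    anchors = sorted(anchors)
    lam = np.zeros(max_age)
    ages = np.arange(1, max_age + 1)
    prev_age, prev_F = anchors[0]
    if prev_F > 0:
        raise ValueError("first anchor must have F = 0")
    for age, F in anchors[1:]:
        if not (age > prev_age and 1.0 > F >= prev_F):
            raise ValueError("anchors must be increasing in age and F")
        h = 1.0 - ((1.0 - F) / (1.0 - prev_F)) ** (1.0 / (age - prev_age))
        lam[(ages > prev_age) & (ages <= age)] = h
        prev_age, prev_F = age, F
    lam[ages > prev_age] = h if len(anchors) > 1 else 0.0
    return lam


# cumulative-risk anchors shaped like registry-scale estimates:
# carriers reach 50% by age 70 for breast cancer, noncarriers 16%;
# ovarian risk is much lower and later for both classes.
DEFAULT_BREAST_ANCHORS = {
    "carrier": [(25, 0.0), (40, 0.10), (50, 0.163), (60, 0.305), (70, 0.50)],
    "noncarrier": [(25, 0.0), (40, 0.011), (50, 0.063), (60, 0.118),
                   (70, 0.16)],
}
DEFAULT_OVARIAN_ANCHORS = {
    "carrier": [(30, 0.0), (50, 0.05), (60, 0.137), (70, 0.215)],
    "noncarrier": [(30, 0.0), (50, 0.004), (60, 0.007), (70, 0.014)],
}

#: sisters per family: median 2, interquartile range 1-3
DEFAULT_SISTER_DIST = {0: 0.10, 1: 0.25, 2: 0.30, 3: 0.20, 4: 0.10, 5: 0.05}
#: daughters per family: median 0, interquartile range 0-1
DEFAULT_DAUGHTER_DIST = {0: 0.55, 1: 0.25, 2: 0.15, 3: 0.05}

#: (mean, sd) of age at last follow-up by role, years
DEFAULT_FOLLOWUP_AGE = {
    "proband": (52.0, 10.0),
    "mother": (68.0, 10.0),
    "sister": (52.0, 12.0),
    "daughter": (30.0, 10.0),
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic registry."""

    q: float = 0.02
    n_families: int = 1600
    gene: str = "BRCA1"
    gamma: float = 0.3
    seed: Optional[int] = None
    max_age: int = 90
    sister_dist: dict = field(
        default_factory=lambda: dict(DEFAULT_SISTER_DIST))
    daughter_dist: dict = field(
        default_factory=lambda: dict(DEFAULT_DAUGHTER_DIST))
    breast_anchors: dict = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in DEFAULT_BREAST_ANCHORS.items()})
    ovarian_anchors: dict = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in DEFAULT_OVARIAN_ANCHORS.items()})
    followup_age: dict = field(
        default_factory=lambda: dict(DEFAULT_FOLLOWUP_AGE))
    p_rrso: float = 0.03
    rrso_age_range: tuple = (35, 60)
    p_rrm: float = 0.01
    rrm_age_range: tuple = (30, 55)
    p_dead: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        for dist in (self.sister_dist, self.daughter_dist):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("family-size distribution must sum to 1")

    def truth_hazards(self, outcome: str) -> HazardTable:
        anchors = (self.breast_anchors if outcome == "breast"
                   else self.ovarian_anchors)
        grid = np.arange(1, self.max_age + 1, dtype=float)
        return HazardTable(
            grid=grid,
            lambda_carrier=hazards_from_anchors(anchors["carrier"],
                                                self.max_age),
            lambda_noncarrier=hazards_from_anchors(anchors["noncarrier"],
                                                   self.max_age))

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["rrso_age_range"] = list(self.rrso_age_range)
        data["rrm_age_range"] = list(self.rrm_age_range)
        data["followup_age"] = {k: [float(m), float(s)]
                                for k, (m, s) in self.followup_age.items()}
        for key in ("breast_anchors", "ovarian_anchors"):
            data[key] = {g: [[float(a), float(f)] for a, f in v]
                         for g, v in data[key].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("rrso_age_range", "rrm_age_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "followup_age" in data:
            data["followup_age"] = {k: tuple(v)
                                    for k, v in data["followup_age"].items()}
        for key in ("breast_anchors", "ovarian_anchors"):
            if key in data:
                data[key] = {g: [tuple(x) for x in v]
                             for g, v in data[key].items()}
        for key in ("sister_dist", "daughter_dist"):
            if key in data:
                data[key] = {int(k): float(v) for k, v in data[key].items()}
        return cls(**data)


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a synthetic registry."""

    genotypes: pd.DataFrame  # family_id, person_id, role, true_carrier
    breast: HazardTable
    ovarian: HazardTable
    q: float
    n_candidates: int
    acceptance_rate: float

    def cumulative_risk(self, outcome: str, group: str, age: float,
                        from_age: float = 0.0) -> float:
        table = self.breast if outcome == "breast" else self.ovarian
        lam = table.hazard(group)
        mask = (table.grid > from_age) & (table.grid <= age)
        return float(1.0 - np.prod(1.0 - lam[mask]))


def _draw_counts(rng, dist: dict, n: int) -> np.ndarray:
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in sorted(dist)], dtype=float)
    return keys[rng.choice(len(keys), size=n, p=probs)]


def _transmit(rng, g_parent1, g_parent2):
    """Offspring mutant-allele counts from two parents' counts."""
    a1 = rng.random(len(g_parent1)) < g_parent1 / 2.0
    a2 = rng.random(len(g_parent2)) < g_parent2 / 2.0
    return a1.astype(np.int64) + a2.astype(np.int64)


def _draw_onset(rng, carrier: np.ndarray, table: HazardTable) -> np.ndarray:
    """Age at onset per woman (np.inf if onset never occurs)."""
    ages = table.grid
    Fc = 1.0 - np.cumprod(1.0 - table.lambda_carrier)
    Fn = 1.0 - np.cumprod(1.0 - table.lambda_noncarrier)
    u = rng.random(len(carrier))
    out = np.full(len(carrier), np.inf)
    for mask, F in ((carrier, Fc), (~carrier, Fn)):
        idx = np.searchsorted(F, u[mask], side="left")
        hit = idx < len(ages)
        vals = np.full(mask.sum(), np.inf)
        vals[hit] = ages[idx[hit]]
        out[mask] = vals
    return out


def _draw_censoring(rng, role: str, n: int, config: SimulationConfig):
    mean, sd = config.followup_age[role]
    age_last = np.clip(np.round(rng.normal(mean, sd, n)), 12, config.max_age)
    rrso = np.where(rng.random(n) < config.p_rrso,
                    rng.integers(config.rrso_age_range[0],
                                 config.rrso_age_range[1] + 1, n),
                    np.inf)
    rrm = np.where(rng.random(n) < config.p_rrm,
                   rng.integers(config.rrm_age_range[0],
                                config.rrm_age_range[1] + 1, n),
                   np.inf)
    dead = rng.random(n) < config.p_dead
    return age_last, rrso, rrm, dead


def _observed_ages(onset_b, onset_o, age_last, rrso, rrm):
    """Recorded diagnosis/surgery ages given the latent onset times.

    A breast diagnosis is recorded if it occurs during follow-up and not
    after a risk-reducing mastectomy (same-age ties count as diagnoses);
    likewise ovarian diagnoses versus RRSO.  Surgeries after the last
    follow-up are unobserved.
    """
    b = np.where((onset_b <= age_last) & (onset_b <= rrm), onset_b, np.inf)
    o = np.where((onset_o <= age_last) & (onset_o <= rrso), onset_o, np.inf)
    rrso_obs = np.where(rrso <= age_last, rrso, np.inf)
    rrm_obs = np.where(rrm <= age_last, rrm, np.inf)
    return b, o, rrso_obs, rrm_obs


def _maybe(x: float) -> Optional[float]:
    return None if np.isinf(x) else float(x)


def simulate_families(config: SimulationConfig,
                      seed: Optional[int] = None
                      ) -> tuple[list[Family], SimulationTruth]:
    """Generate one ascertained registry plus its truth sidecar.

    Candidate families are generated until ``n_families`` pass
    ascertainment (the proband has a recorded breast cancer diagnosis).
    Relatives are then masked to ``config.gamma`` genotyping coverage;
    probands are never masked.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required for simulation")
    rng = np.random.default_rng(seed)
    hwe = np.asarray(hwe_genotype_freqs(config.q))
    breast = config.truth_hazards("breast")
    ovarian = config.truth_hazards("ovarian")

    families: list[Family] = []
    truth_rows: list[dict] = []
    n_candidates = 0
    accept_est = 0.1

    while len(families) < config.n_families:
        need = config.n_families - len(families)
        batch = max(1024, int(need / max(accept_est, 0.01)))
        n_candidates += batch

        g_mother = rng.choice(3, size=batch, p=hwe)
        g_father = rng.choice(3, size=batch, p=hwe)
        g_pro = _transmit(rng, g_mother, g_father)
        onset_b = _draw_onset(rng, g_pro >= 1, breast)
        onset_o = _draw_onset(rng, g_pro >= 1, ovarian)
        age_last, rrso, rrm, dead = _draw_censoring(rng, "proband", batch,
                                                    config)
        b, o, rrso_obs, rrm_obs = _observed_ages(onset_b, onset_o,
                                                 age_last, rrso, rrm)
        keep = np.flatnonzero(~np.isinf(b))[:need]

        if n_candidates >= 20000 and \
                (len(families) + len(keep)) / n_candidates < 1e-4:
            raise SimulationError(
                "ascertainment acceptance rate below 1e-4: no (or almost "
                "no) candidate probands develop breast cancer under the "
                "configured hazards"
            )
        if len(keep) == 0:
            continue
        accept_est = max(len(keep) / batch, 0.001)

        n_acc = len(keep)
        n_sis = _draw_counts(rng, config.sister_dist, n_acc)
        n_dau = _draw_counts(rng, config.daughter_dist, n_acc)

        # sisters share the proband's parents; daughters get an HWE mate
        sis_fam = np.repeat(np.arange(n_acc), n_sis)
        g_sis = _transmit(rng, g_mother[keep][sis_fam],
                          g_father[keep][sis_fam])
        dau_fam = np.repeat(np.arange(n_acc), n_dau)
        g_mate = rng.choice(3, size=len(dau_fam), p=hwe)
        g_dau = _transmit(rng, g_pro[keep][dau_fam], g_mate)

        rel_groups = []
        for role, fam_idx, g in (("mother", np.arange(n_acc),
                                  g_mother[keep]),
                                 ("sister", sis_fam, g_sis),
                                 ("daughter", dau_fam, g_dau)):
            nrel = len(fam_idx)
            onb = _draw_onset(rng, g >= 1, breast)
            ono = _draw_onset(rng, g >= 1, ovarian)
            al, rs, rm, dd = _draw_censoring(rng, role, nrel, config)
            rb, ro, rso, rrmo = _observed_ages(onb, ono, al, rs, rm)
            rel_groups.append((role, fam_idx, g, rb, ro, rso, rrmo, al, dd))

        for i in range(n_acc):
            fid = f"F{len(families) + 1:05d}"
            k = keep[i]
            proband = IndividualRecord(
                family_id=fid, person_id=f"{fid}-p", role="proband",
                genotype="carrier" if g_pro[k] >= 1 else "noncarrier",
                age_breast_dx=_maybe(b[k]), age_ovarian_dx=_maybe(o[k]),
                age_rrso=_maybe(rrso_obs[k]), age_rrm=_maybe(rrm_obs[k]),
                age_last=float(age_last[k]),
                vital="dead" if dead[k] else "alive")
            truth_rows.append({"family_id": fid, "person_id": f"{fid}-p",
                               "role": "proband",
                               "true_carrier": bool(g_pro[k] >= 1)})
            relatives = []
            for role, fam_idx, g, rb, ro, rso, rrmo, al, dd in rel_groups:
                sel = np.flatnonzero(fam_idx == i)
                for nth, jj in enumerate(sel, start=1):
                    pid = (f"{fid}-m" if role == "mother"
                           else f"{fid}-{role[0]}{nth}")
                    relatives.append(IndividualRecord(
                        family_id=fid, person_id=pid, role=role,
                        genotype="carrier" if g[jj] >= 1 else "noncarrier",
                        age_breast_dx=_maybe(rb[jj]),
                        age_ovarian_dx=_maybe(ro[jj]),
                        age_rrso=_maybe(rso[jj]), age_rrm=_maybe(rrmo[jj]),
                        age_last=float(al[jj]),
                        vital="dead" if dd[jj] else "alive"))
                    truth_rows.append({"family_id": fid, "person_id": pid,
                                       "role": role,
                                       "true_carrier": bool(g[jj] >= 1)})
            families.append(Family(
                family_id=fid, proband=proband, relatives=relatives,
                proband_gene_status=(config.gene if g_pro[k] >= 1
                                     else NEGATIVE_STATUS)))

    families = mask_genotypes(families, config.gamma, rng=rng)
    truth = SimulationTruth(
        genotypes=pd.DataFrame(truth_rows),
        breast=breast, ovarian=ovarian, q=config.q,
        n_candidates=n_candidates,
        acceptance_rate=config.n_families / n_candidates)
    return families, truth


def mask_genotypes(families: Sequence[Family], gamma: float,
                   seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None) -> list[Family]:
    """Retain each relative's genotype with probability ``gamma``.

    Emulates partial genotyping of relatives; probands are never masked.
    Returns new Family objects (inputs are untouched).
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for fam in families:
        keep = rng.random(len(fam.relatives)) < gamma
        relatives = [rel if kept else rel.with_genotype("untested")
                     for rel, kept in zip(fam.relatives, keep)]
        out.append(Family(family_id=fam.family_id, proband=fam.proband,
                          relatives=relatives,
                          proband_gene_status=fam.proband_gene_status))
    return out
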