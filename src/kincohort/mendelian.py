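"""Mendelian carrier probabilities for first-degree relatives.

The kin-cohort design knows the proband's genotype but usually not her
relatives'.  Under Hardy-Weinberg equilibrium at mutant allele frequency q
and Mendelian transmission, the probability that a mother, daughter, or
sister of the proband carries the mutation is an exact function of the
proband's carrier status and the relation.  Carrier status pools the
heterozygote and the (vanishingly rare) homozygote: the model is dominant,
as appropriate for BRCA1/2.

Observed relative genotypes override the Mendelian prior: a genotyped
relative has mixing weight exactly 0 or 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .records import Family, IndividualRecord, RELATIVE_ROLES

__all__ = [
    "GenotypeModel",
    "MixingWeight",
    "hwe_genotype_freqs",
    "relative_carrier_prob",
    "mixing_weight",
    "estimate_allele_frequency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenotypeModel:
    """Dominant single-locus model at mutant allele frequency ``q``."""

    q: float
    gene: str = "BRCA1"

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"allele frequency q={self.q} outside [0, 1]")


@dataclass(frozen=True)
class MixingWeight:
    """P(relative is a carrier) given proband genotype and any observed
    genotype; exactly 0 or 1 when the relative was genotyped."""

    person_id: str
    p: float
    observed: bool = False


def hwe_genotype_freqs(q: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype frequencies ((1-q)^2, 2q(1-q), q^2).

    Ordered by mutant-allele count (aa, Aa, AA) where ``A`` is the mutant
    allele.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"allele frequency q={q} outside [0, 1]")
    p = 1.0 - q
    return (p * p, 2.0 * q * p, q * q)


def _child_dist(gm: int, gf: int) -> np.ndarray:
    """Offspring genotype distribution given parental mutant-allele counts."""
    out = np.zeros(3)
    tm, tf = gm / 2.0, gf / 2.0  # P(transmit mutant allele)
    for am, pa in ((0, 1 - tm), (1, tm)):
        for af, pb in ((0, 1 - tf), (1, tf)):
            out[am + af] += pa * pb
    return out


def _joint_parent_offspring(q: float) -> np.ndarray:
    """Joint distribution J[g_parent, g_child] with a random HWE mate."""
    hwe = np.asarray(hwe_genotype_freqs(q))
    joint = np.zeros((3, 3))
    for gp in range(3):
        for gm in range(3):
            joint[gp] += hwe[gp] * hwe[gm] * _child_dist(gp, gm)
    return joint


def _joint_siblings(q: float) -> np.ndarray:
    """Joint distribution J[g_sib1, g_sib2] over two full siblings with
    HWE parents and independent transmissions."""
    hwe = np.asarray(hwe_genotype_freqs(q))
    joint = np.zeros((3, 3))
    for gm in range(3):
        for gf in range(3):
            child = _child_dist(gm, gf)
            joint += hwe[gm] * hwe[gf] * np.outer(child, child)
    return joint


def relative_carrier_prob(proband_status: str, relation: str,
                          model: GenotypeModel,
                          method: str = "exact") -> float:
    """P(relative carries the mutation | proband carrier status).

    ``method="exact"`` enumerates the joint genotype distribution:
    parent-offspring pairs via allele transmission with a random HWE mate,
    siblings via both parents' HWE genotypes and independent transmissions,
    then conditions on the proband's dominant-pooled class.  Mother and
    daughter are symmetric; the sibling probability differs from the
    parent-offspring one for q > 0.

    ``method="half"`` is the textbook rare-allele approximation: 1/2 for
    relatives of carrier probands, 0 otherwise.
    """
    if relation not in RELATIVE_ROLES:
        raise ValueError(f"unknown relation {relation!r}")
    if proband_status not in ("carrier", "noncarrier"):
        raise ValueError(f"unknown proband status {proband_status!r}")
    if method == "half":
        return 0.5 if proband_status == "carrier" else 0.0
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    if relation == "sister":
        joint = _joint_siblings(model.q)
    else:  # mother / daughter: parent-offspring, symmetric under HWE
        joint = _joint_parent_offspring(model.q)
    # axis 0 = proband, axis 1 = relative; carrier class = >=1 mutant allele
    if proband_status == "carrier":
        mass = joint[1:, :].sum(axis=0)
    else:
        mass = joint[0, :]
    total = mass.sum()
    if total == 0.0:  # monomorphic q (0 or 1) makes a class impossible
        return 0.0 if proband_status == "noncarrier" else 1.0
    return float(mass[1:].sum() / total)


def mixing_weight(relative: IndividualRecord, proband_status: str,
                  model: GenotypeModel, method: str = "exact") -> MixingWeight:
    """Carrier probability for one relative, using her observed genotype
    when available and the Mendelian prior otherwise."""
    if relative.genotype == "carrier":
        return MixingWeight(relative.person_id, 1.0, observed=True)
    if relative.genotype == "noncarrier":
        return MixingWeight(relative.person_id, 0.0, observed=True)
    p = relative_carrier_prob(proband_status, relative.role, model, method)
    return MixingWeight(relative.person_id, p, observed=False)


def estimate_allele_frequency(families: Iterable[Family], gene: str) -> float:
    """Allele frequency as half the carrier frequency among probands.

    This is the registry-based plug-in estimate: with n_c carrier probands
    among n probands, q_hat = 0.5 * n_c / n.  In an ascertained high-risk
    registry this over-states the population frequency; see the methods
    note for when to prefer an external q.
    """
    families = list(families)
    if not families:
        raise ValueError("no families: cannot estimate allele frequency")
    n_carrier = sum(1 for f in families if f.proband_gene_status == gene)
    q_hat = 0.5 * n_carrier / len(families)
    if n_carrier == 0:
        logger.warning("no %s carrier probands: q_hat = 0 (degenerate model)",
                       gene)
    return q_hat
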