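"""Shared fixtures: hand-built families and count-matched registries."""

from __future__ import annotations

import numpy as np
import pytest

from kincohort import Family, IndividualRecord


def make_person(fid, pid, role, genotype="untested", breast=None,
                ovarian=None, rrso=None, rrm=None, last=60.0, vital="alive"):
    return IndividualRecord(
        family_id=fid, person_id=pid, role=role, genotype=genotype,
        age_breast_dx=breast, age_ovarian_dx=ovarian, age_rrso=rrso,
        age_rrm=rrm, age_last=last, vital=vital)


def build_count_registry(group_sizes: dict[str, tuple[int, int]],
                         relatives_per_family: int = 5) -> list[Family]:
    """Families whose relatives reproduce given (n_relatives, n_cases)
    counts per proband group.

    Cases are breast cancer diagnoses at age 45 with follow-up to 60;
    unaffected relatives are censored at 60.  Used to rebuild published
    count tables as concrete registries.
    """
    families = []
    for group, (n_rel, n_cases) in group_sizes.items():
        carrier = group != "negative"
        built = 0
        fam_no = 0
        while built < n_rel:
            fam_no += 1
            fid = f"{group}-{fam_no:04d}"
            proband = make_person(
                fid, f"{fid}-p", "proband",
                genotype="carrier" if carrier else "noncarrier",
                breast=40.0, last=50.0)
            rels = []
            for i in range(min(relatives_per_family, n_rel - built)):
                idx = built + i
                rels.append(make_person(
                    fid, f"{fid}-r{i}", "sister",
                    breast=45.0 if idx < n_cases else None))
            built += len(rels)
            families.append(Family(
                family_id=fid, proband=proband, relatives=rels,
                proband_gene_status=group))
    return families


@pytest.fixture
def toy_family() -> Family:
    fid = "T001"
    proband = make_person(fid, "p", "proband", genotype="carrier",
                          breast=42.0, last=55.0)
    relatives = [
        make_person(fid, "m", "mother", breast=48.0, last=70.0),
        make_person(fid, "s1", "sister", genotype="carrier", last=50.0),
        make_person(fid, "s2", "sister", ovarian=44.0, last=61.0),
        make_person(fid, "d1", "daughter", genotype="noncarrier",
                    last=30.0),
    ]
    return Family(family_id=fid, proband=proband, relatives=relatives,
                  proband_gene_status="BRCA1")


@pytest.fixture
def small_registry(toy_family) -> list[Family]:
    """A handful of families spanning carrier and negative probands."""
    rng = np.random.default_rng(42)
    families = [toy_family]
    for i in range(2, 9):
        fid = f"T{i:03d}"
        carrier = i % 3 == 0
        proband = make_person(
            fid, f"{fid}-p", "proband",
            genotype="carrier" if carrier else "noncarrier",
            breast=float(rng.integers(35, 55)), last=60.0)
        rels = []
        for k in range(int(rng.integers(1, 4))):
            onset = float(rng.integers(35, 75)) if rng.random() < 0.3 else None
            last = float(rng.integers(40, 80))
            if onset is not None and onset > last:
                onset = last
            rels.append(make_person(fid, f"{fid}-r{k}",
                                    ["mother", "sister", "daughter"][k % 3],
                                    breast=onset, last=last))
        families.append(Family(
            family_id=fid, proband=proband, relatives=rels,
            proband_gene_status="BRCA1" if carrier else "negative"))
    return families
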