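"""Reading and writing the kin-cohort table, plus descriptive summaries.

The on-disk format is one-row-per-individual delimited text with header::

    family_id,person_id,role,gene,genotype,age_breast_dx,age_ovarian_dx,
    age_rrso,age_rrm,age_last,vital

The ``gene`` column names the gene for which the stated ``genotype``
applies (empty for untested individuals).  Absent ages are empty fields,
never 0.  Lines starting with ``#`` are comments (run provenance headers).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .records import (
    EXTENDED_ROLES,
    GENOTYPES,
    RELATIVE_ROLES,
    Family,
    IndividualRecord,
    ValidationError,
    derive_followup,
)

__all__ = [
    "COLUMNS",
    "ParseError",
    "read_kincohort_table",
    "write_kincohort_table",
    "incidence_summary",
]

logger = logging.getLogger(__name__)

COLUMNS = [
    "family_id", "person_id", "role", "gene", "genotype",
    "age_breast_dx", "age_ovarian_dx", "age_rrso", "age_rrm",
    "age_last", "vital",
]

_AGE_COLUMNS = [c for c in COLUMNS if c.startswith("age_")]

#: proband gene-status labels for families whose proband tested negative
NEGATIVE_STATUS = "negative"


class ParseError(ValueError):
    """A malformed row or header in a kin-cohort table."""


def _read_raw(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#",
                     keep_default_na=False, skip_blank_lines=True)
    if list(df.columns) != COLUMNS:
        raise ParseError(
            f"{path}: expected header {','.join(COLUMNS)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    return df


def read_kincohort_table(path, gene: str, sep: str = ",") -> list[Family]:
    """Read a kin-cohort table and group rows into families.

    ``gene`` is the gene under analysis (e.g. ``"BRCA1"``).  A relative's
    genotype is honoured only when her ``gene`` field matches; genotypes
    recorded for a different gene are mapped to ``untested``.  The proband's
    gene status is taken from her own row (``negative`` when she tested
    noncarrier).  Relatives with more distant roles are dropped with a
    warning, as are individuals lacking any usable follow-up age.
    """
    df = _read_raw(path, sep)
    # line numbers in the physical file: header is line 1
    lines = df.index.to_numpy() + 2

    records: dict[str, dict] = {}  # insertion order = file order
    n_dropped_distant = 0
    n_dropped_no_followup = 0

    for pos, row in enumerate(df.itertuples(index=False)):
        line = lines[pos]
        role = row.role.strip()
        if role in EXTENDED_ROLES:
            n_dropped_distant += 1
            continue
        if role not in RELATIVE_ROLES and role != "proband":
            raise ParseError(f"line {line}: unknown role {role!r}")
        genotype = row.genotype.strip() or "untested"
        if genotype not in GENOTYPES:
            raise ParseError(f"line {line}: unknown genotype {genotype!r}")
        ages = {}
        for col in _AGE_COLUMNS:
            raw = getattr(row, col).strip()
            if raw == "":
                ages[col] = None
                continue
            try:
                ages[col] = float(raw)
            except ValueError:
                raise ParseError(
                    f"line {line}: non-numeric {col} value {raw!r}"
                ) from None
        if ages["age_last"] is None:
            # no time-to-event data at all: excluded from analysis
            n_dropped_no_followup += 1
            continue

        row_gene = row.gene.strip()
        if role == "proband":
            status = row_gene if genotype == "carrier" else NEGATIVE_STATUS
            # the analysis is carrier vs noncarrier for `gene` only
            analysis_genotype = "carrier" if status == gene else "noncarrier"
        else:
            status = None
            analysis_genotype = genotype if row_gene == gene else "untested"
            if genotype == "untested":
                analysis_genotype = "untested"

        try:
            rec = IndividualRecord(
                family_id=row.family_id.strip(),
                person_id=row.person_id.strip(),
                role=role,
                genotype=analysis_genotype,
                vital=(row.vital.strip() or "alive"),
                **ages,
            )
        except ValidationError as exc:
            raise ParseError(f"line {line}: {exc}") from exc

        fam = records.setdefault(rec.family_id, {"proband": None,
                                                 "relatives": [],
                                                 "status": None})
        if role == "proband":
            if fam["proband"] is not None:
                raise ValidationError(
                    f"family {rec.family_id!r}: duplicate proband"
                )
            fam["proband"] = rec
            fam["status"] = status
        else:
            fam["relatives"].append(rec)

    if n_dropped_distant:
        logger.warning("dropped %d non-first-degree relatives",
                       n_dropped_distant)
    if n_dropped_no_followup:
        logger.warning("excluded %d individuals with no usable "
                       "time-to-event data", n_dropped_no_followup)

    families = []
    for fid, fam in records.items():
        if fam["proband"] is None:
            raise ValidationError(f"family {fid!r}: missing proband")
        families.append(Family(family_id=fid, proband=fam["proband"],
                               relatives=fam["relatives"],
                               proband_gene_status=fam["status"]))
    return families


def families_to_frame(families: Iterable[Family]) -> pd.DataFrame:
    """Flatten families into the on-disk column layout."""
    rows = []
    for fam in families:
        positive = fam.proband_gene_status != NEGATIVE_STATUS
        for person in fam.members:
            if person.role == "proband":
                gene = fam.proband_gene_status if positive else ""
                genotype = "carrier" if positive else "noncarrier"
            else:
                gene = "" if person.genotype == "untested" else "*"
                genotype = person.genotype
            rows.append({
                "family_id": fam.family_id,
                "person_id": person.person_id,
                "role": person.role,
                "gene": gene,
                "genotype": genotype,
                "age_breast_dx": person.age_breast_dx,
                "age_ovarian_dx": person.age_ovarian_dx,
                "age_rrso": person.age_rrso,
                "age_rrm": person.age_rrm,
                "age_last": person.age_last,
                "vital": person.vital,
            })
    return pd.DataFrame(rows, columns=COLUMNS)


def write_kincohort_table(families: Iterable[Family], path, sep: str = ",",
                          gene: Optional[str] = None,
                          header_comment: Optional[str] = None) -> None:
    """Write families in the kin-cohort table format.

    ``gene`` fills the gene column for genotyped individuals (a file is
    written per-analysis, so all stated genotypes refer to one gene).
    ``header_comment`` lines, if given, are prefixed with ``#``.
    """
    df = families_to_frame(families)
    if gene is not None:
        df.loc[df["gene"] == "*", "gene"] = gene
    else:
        df.loc[df["gene"] == "*", "gene"] = ""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False, na_rep="")


_GROUP_ORDER = ("BRCA1", "BRCA2", NEGATIVE_STATUS)


def incidence_summary(families: Iterable[Family], outcome: str) -> pd.DataFrame:
    """Per-proband-group counts of relatives and outcome cases.

    Groups are defined by the proband's gene status.  Only relatives with
    derivable follow-up contribute.  ``percent`` is 100 x cases / relatives,
    reported as NaN (undefined) for empty groups.
    """
    counts: dict[str, list[int]] = {}
    order: list[str] = []
    for fam in families:
        group = fam.proband_gene_status
        if group not in counts:
            counts[group] = [0, 0]
            order.append(group)
        for rel in fam.relatives:
            try:
                fu = derive_followup(rel, outcome)
            except ValidationError:
                continue
            counts[group][0] += 1
            counts[group][1] += fu.event
    order.sort(key=lambda g: (_GROUP_ORDER.index(g)
                              if g in _GROUP_ORDER else len(_GROUP_ORDER), g))
    rows = []
    for group in order:
        n_rel, n_cases = counts[group]
        pct = 100.0 * n_cases / n_rel if n_rel else np.nan
        rows.append({"group": group, "n_relatives": n_rel,
                     "n_cases": n_cases, "percent": pct})
    return pd.DataFrame(rows, columns=["group", "n_relatives",
                                       "n_cases", "percent"])
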