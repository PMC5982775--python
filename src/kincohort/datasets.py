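"""Bundled reference tables.

The meta-analysis input is the published table of age-specific breast
cancer penetrance estimates (percent, with 95% CIs) for Asian BRCA1/2
mutation carriers from the three available cohorts: a Korean segregation
study, a Beijing kin-cohort study, and a Hong Kong kin-cohort study.
"""

from __future__ import annotations

import io

import pandas as pd

from .meta import StudyEstimate

__all__ = ["load_asian_breast_studies", "asian_breast_studies"]

_ASIAN_BREAST_CSV = """\
study,gene,age_interval,estimate,ci_low,ci_high
Korea,BRCA1,20-40,10,2,45
Beijing,BRCA1,20-40,2.2,0,4.4
HongKong,BRCA1,20-40,10.0,4.7,15.7
Korea,BRCA1,20-50,27,5,84
Beijing,BRCA1,20-50,9.9,3.3,17.2
HongKong,BRCA1,20-50,16.3,8.6,25.0
Korea,BRCA1,20-60,41,9,95
Beijing,BRCA1,20-60,29.3,17.6,47.1
HongKong,BRCA1,20-60,30.5,18.0,46.6
Korea,BRCA1,20-70,49,11,98
Beijing,BRCA1,20-70,37.9,24.1,54.4
HongKong,BRCA1,20-70,53.7,34.5,71.6
Korea,BRCA2,20-40,6,3,15
Beijing,BRCA2,20-40,1.2,0,3.1
HongKong,BRCA2,20-40,6.7,3.2,11.0
Korea,BRCA2,20-50,18,8,39
Beijing,BRCA2,20-50,10.7,9.6,16.9
HongKong,BRCA2,20-50,21.1,12.3,31.1
Korea,BRCA2,20-60,28,13,56
Beijing,BRCA2,20-60,27.2,19.0,38.5
HongKong,BRCA2,20-60,31.4,21.6,42.6
Korea,BRCA2,20-70,35,16,65
Beijing,BRCA2,20-70,36.5,26.7,51.8
HongKong,BRCA2,20-70,48.3,31.8,68.5
"""


def load_asian_breast_studies() -> pd.DataFrame:
    """The transcribed per-study penetrance table as a DataFrame."""
    return pd.read_csv(io.StringIO(_ASIAN_BREAST_CSV))


def asian_breast_studies(gene: str, age_interval: str) -> list[StudyEstimate]:
    """Study estimates for one gene and age interval."""
    df = load_asian_breast_studies()
    sel = df[(df["gene"] == gene) & (df["age_interval"] == age_interval)]
    if sel.empty:
        raise KeyError(f"no rows for {gene} {age_interval}")
    return [StudyEstimate(study=r.study, estimate=r.estimate,
                          ci_low=r.ci_low, ci_high=r.ci_high,
                          age_interval=r.age_interval)
            for r in sel.itertuples(index=False)]
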