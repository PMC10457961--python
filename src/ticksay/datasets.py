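"""Bundled summary data from a published adult-immersion-test study.

A published bioassay of an entomopathogenic *Aspergillus flavus* isolate
against engorged *Rhipicephalus microplus* females (control + four conidial
doses, four replicates of ten ticks each) reports only per-group mean ± SD.
These summaries — and replicate-level values algebraically reconstructed to
match them exactly — are bundled here as worked inputs for the summary-ANOVA
and Tukey-letter machinery, and for regression tests against the published
statistics (mortality F(4,15) = 11.37, letters a,a,a,b,b, ...).

Replicate reconstruction is not unique; any set with the printed mean and
sample SD yields the same ANOVA, and the bundled sets were chosen as small
integer percentages of 10-tick units.
"""

from __future__ import annotations

from .group_stats import GroupSummary

__all__ = [
    "AIT_GROUP_LABELS",
    "AIT_MORTALITY_SUMMARY",
    "AIT_MORBIDITY_SUMMARY",
    "AIT_EPI_SUMMARY",
    "AIT_MORTALITY_REPLICATES",
    "AIT_MORBIDITY_REPLICATES",
    "AFLATOXIN_B1_MG_KG",
    "AFLATOXIN_B2_MG_KG",
    "SCLEROTIUM_DIAMETER_UM",
    "AFLF_GENE_LENGTH_BP",
    "AFLF_FRAGMENT_SPANS",
    "AFLF_ACTIVE_SITE_POSITION",
]

#: Dose groups, control first, then conidia/mL.
AIT_GROUP_LABELS = ("control", "1e5", "1e6", "1e7", "1e8")

#: Published mortality % per group: mean (5,10,15,50,50), SD to one decimal.
AIT_MORTALITY_SUMMARY = GroupSummary(
    labels=AIT_GROUP_LABELS,
    means=(5.0, 10.0, 15.0, 50.0, 50.0),
    sds=(10.0, 14.1, 5.8, 14.1, 18.3),
    ns=(4, 4, 4, 4, 4),
)

#: Published morbidity % per group.
AIT_MORBIDITY_SUMMARY = GroupSummary(
    labels=AIT_GROUP_LABELS,
    means=(2.5, 90.0, 100.0, 100.0, 100.0),
    sds=(5.0, 11.5, 0.0, 0.0, 0.0),
    ns=(4, 4, 4, 4, 4),
)

#: Published egg-production-index % per group.
AIT_EPI_SUMMARY = GroupSummary(
    labels=AIT_GROUP_LABELS,
    means=(53.4, 50.7, 53.4, 39.8, 48.6),
    sds=(2.0, 5.7, 6.8, 11.2, 2.5),
    ns=(4, 4, 4, 4, 4),
)

#: Replicate mortality % values reconstructed to match the published
#: means/SDs exactly (means 5,10,15,50,50; SDs 10,14.14,5.77,14.14,18.26).
AIT_MORTALITY_REPLICATES = (
    (0.0, 0.0, 0.0, 20.0),
    (0.0, 0.0, 10.0, 30.0),
    (10.0, 10.0, 20.0, 20.0),
    (40.0, 40.0, 50.0, 70.0),
    (30.0, 40.0, 60.0, 70.0),
)

#: Replicate morbidity % values reconstructed the same way
#: (means 2.5,90,100,100,100; SDs 5,11.55,0,0,0).
AIT_MORBIDITY_REPLICATES = (
    (0.0, 0.0, 0.0, 10.0),
    (80.0, 80.0, 100.0, 100.0),
    (100.0, 100.0, 100.0, 100.0),
    (100.0, 100.0, 100.0, 100.0),
    (100.0, 100.0, 100.0, 100.0),
)

#: HPLC aflatoxin concentrations of the isolate's extract (mg/kg).
AFLATOXIN_B1_MG_KG = 424.2
AFLATOXIN_B2_MG_KG = 7.2

#: Mean sclerotium diameter of the isolate (µm); over 400 µm = morphotype L.
SCLEROTIUM_DIAMETER_UM = 418.82

#: The A. parasiticus reference aflF gene and how the isolate's two genomic
#: fragments of it project back onto the reference: 364 bp and 221 bp,
#: overlapping by 9 bp, with the first 574 bp (including the ~position-207
#: active site) absent.
AFLF_GENE_LENGTH_BP = 1149
AFLF_FRAGMENT_SPANS = ((575, 938), (930, 1150))
AFLF_ACTIVE_SITE_POSITION = 207
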