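"""Canonical vocabularies and published reference tables.

The analysis concerns ischemic-heart-disease (stable angina) care pathways in a
national reimbursement register.  Care events fall into three categories:

* ``E``  -- noninvasive, nonimaging testing (stress electrocardiography),
* ``NI`` -- noninvasive imaging (stress echocardiography, SPECT),
* ``I``  -- invasive procedures (coronary angiography, PCI, CABG).

A care episode ("event series") is labelled by the order of first occurrence of
these categories, giving exactly 15 possible pathway types.

This module also carries the published three-cluster characterization of the
Hungarian primary-care-center network (2004-2008) that serves (a) as the default
archetype profiles for the synthetic registry and (b) as the printed-number input
for the aggregation-identity checks, plus the averaged per-procedure
reimbursement tariff table of the same period.
"""

from __future__ import annotations

from itertools import permutations

# --- procedure vocabulary -------------------------------------------------

ECG_STRESS = "ECG_STRESS"
ECHO_STRESS = "ECHO_STRESS"
SPECT = "SPECT"
CA = "CA"
PCI = "PCI"
CABG = "CABG"
DEATH = "DEATH"

PROCEDURES = (ECG_STRESS, ECHO_STRESS, SPECT, CA, PCI, CABG)

#: procedure -> care category (total over the six procedures; DEATH carries none)
PROCEDURE_CATEGORY = {
    ECG_STRESS: "E",
    ECHO_STRESS: "NI",
    SPECT: "NI",
    CA: "I",
    PCI: "I",
    CABG: "I",
}

CATEGORIES = ("E", "NI", "I")

#: care level names used for dominant-provider voting
LEVEL_CATEGORY = {"primary": "E", "secondary": "NI", "tertiary": "I"}

#: deterministic same-day ordering: category rank, then procedure code
CATEGORY_RANK = {"E": 0, "NI": 1, "I": 2}

REVASCULARIZATION_PROCEDURES = (PCI, CABG)


def enumerate_series_types() -> list[str]:
    """All hyphen-joins of non-empty ordered selections of distinct categories.

    3 singletons + 6 ordered pairs + 6 orderings of the full triple = 15.
    """
    labels = []
    for r in (1, 2, 3):
        for combo in permutations(CATEGORIES, r):
            labels.append("-".join(combo))
    return labels


#: the fixed canonical ordering of the 15 pathway types used everywhere
SERIES_TYPES = (
    "E", "E-NI", "E-NI-I", "E-I", "E-I-NI",
    "NI", "NI-E", "NI-E-I", "NI-I", "NI-I-E",
    "I", "I-E", "I-E-NI", "I-NI", "I-NI-E",
)

SERIES_TYPE_INDEX = {t: i for i, t in enumerate(SERIES_TYPES)}

# --- averaged reimbursement tariffs (HUF; EUR at the Dec 2008 rate) -------

TARIFF_HUF = {
    ECG_STRESS: 3408,
    ECHO_STRESS: 12962,
    SPECT: 35379,
    CA: 145274,
    PCI: 804834,
    CABG: 1262914,
}

TARIFF_EUR = {
    ECG_STRESS: 13,
    ECHO_STRESS: 49,
    SPECT: 134,
    CA: 549,
    PCI: 3040,
    CABG: 4770,
}

# --- published three-cluster characterization -----------------------------

#: per-cluster pathway-type distribution, percent, canonical type order
REFERENCE_CLUSTER_SPECTRA_PCT = {
    1: (75.61, 2.32, 0.51, 5.09, 0.08, 3.27, 0.02, 0.01, 0.58, 0.09,
        10.28, 1.88, 0.03, 0.16, 0.01),
    2: (76.49, 3.84, 0.80, 3.39, 0.12, 6.55, 0.14, 0.04, 1.15, 0.12,
        6.04, 1.02, 0.04, 0.17, 0.01),
    3: (75.99, 3.44, 0.71, 4.41, 0.17, 4.30, 0.08, 0.02, 0.75, 0.11,
        8.18, 1.40, 0.05, 0.26, 0.05),
}

#: series counts behind each cluster column
REFERENCE_CLUSTER_N = {1: 130327, 2: 217514, 3: 158246}

REFERENCE_WHOLE_POPULATION_N = 506087

#: pooled whole-population distribution, percent, canonical type order
REFERENCE_WHOLE_POPULATION_PCT = (
    76.11, 3.33, 0.70, 4.15, 0.12, 5.00, 0.09, 0.02, 0.88, 0.11,
    7.80, 1.36, 0.04, 0.19, 0.02,
)

#: outcome rows of the cluster characterization (percent / HUF)
REFERENCE_CLUSTER_REVASC_PCT = {1: 4.63, 2: 3.09, 3: 4.05}
REFERENCE_CLUSTER_MORT365_PCT = {1: 1.38, 2: 1.45, 3: 1.61}
REFERENCE_CLUSTER_AVG_COST_HUF = {1: 75783, 2: 54182, 3: 66953}
REFERENCE_WHOLE_REVASC_PCT = 3.79
REFERENCE_WHOLE_MORT365_PCT = 1.48
REFERENCE_WHOLE_AVG_COST_HUF = 63738

#: average intra-cluster correlation reported for the three clusters
REFERENCE_INTRACLUSTER_CORR = {1: 0.38, 2: 0.12, 3: 0.37}

#: 365-day mortality by series type, percent (the pathway-level summary table);
#: the I-NI-E entry is unreported there and reuses the I-NI value.
REFERENCE_MORTALITY_BY_TYPE_PCT = (
    0.77, 0.76, 0.64, 1.62, 0.45, 2.33, 1.19, 0.72, 2.83, 0.71,
    8.03, 1.64, 1.75, 4.56, 4.56,
)
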