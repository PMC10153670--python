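"""Published benchmark test accuracies of eight classifiers on UCI datasets.

These are printed results collected from the spiking-network literature for
five small UCI classification datasets (Liver, Breast cancer, PIMA, Iris,
Wine); they are inputs to the rank-aggregation analysis, not outputs of this
package.  Accuracies are mean test accuracy in percent under repeated
five-fold cross-validation.  The Sonar dataset is excluded because not all
approaches report it.
"""

from __future__ import annotations

__all__ = [
    "PUBLISHED_TEST_ACCURACY",
    "PUBLISHED_TRAIN_ACCURACY",
    "PUBLISHED_AVERAGE_RANK",
    "APPROACHES",
]

APPROACHES = ["SpikeProp", "SWAT", "SRESN", "TMM-SNN", "GE-SNN",
              "ANN", "C-STNet", "P-STNet"]

#: mean test accuracy (%) per dataset and approach
PUBLISHED_TEST_ACCURACY: dict[str, dict[str, float]] = {
    "Liver": {
        "SpikeProp": 65.1, "SWAT": 60.9, "SRESN": 59.7, "TMM-SNN": 70.4,
        "GE-SNN": 67.2, "ANN": 71.8, "C-STNet": 69.0, "P-STNet": 72.0,
    },
    "Breast cancer": {
        "SpikeProp": 97.2, "SWAT": 95.8, "SRESN": 97.2, "TMM-SNN": 97.2,
        "GE-SNN": 95.9, "ANN": 97.1, "C-STNet": 97.1, "P-STNet": 97.3,
    },
    "PIMA": {
        "SpikeProp": 76.2, "SWAT": 72.1, "SRESN": 69.9, "TMM-SNN": 78.1,
        "GE-SNN": 74.8, "ANN": 77.4, "C-STNet": 78.2, "P-STNet": 77.4,
    },
    "Iris": {
        "SpikeProp": 96.7, "SWAT": 92.4, "SRESN": 97.3, "TMM-SNN": 97.2,
        "GE-SNN": 93.9, "ANN": 97.1, "C-STNet": 97.7, "P-STNet": 97.6,
    },
    "Wine": {
        "SpikeProp": 96.8, "SWAT": 92.3, "SRESN": 91.0, "TMM-SNN": 97.5,
        "GE-SNN": 86.8, "ANN": 99.1, "C-STNet": 98.8, "P-STNet": 99.1,
    },
}

#: mean training accuracy (%) for the same table (used for generalization
#: gaps); Sonar included where printed
PUBLISHED_TRAIN_ACCURACY: dict[str, dict[str, float]] = {
    "Sonar": {"SpikeProp": 84.7, "ANN": 95.8, "C-STNet": 97.8,
              "P-STNet": 96.3},
    "Liver": {
        "SpikeProp": 71.5, "SWAT": 74.8, "SRESN": 60.4, "TMM-SNN": 74.2,
        "GE-SNN": 76.4, "ANN": 74.6, "C-STNet": 69.4, "P-STNet": 72.3,
    },
    "Breast cancer": {
        "SpikeProp": 97.3, "SWAT": 96.5, "SRESN": 97.7, "TMM-SNN": 97.4,
        "GE-SNN": 97.8, "ANN": 97.5, "C-STNet": 97.4, "P-STNet": 97.4,
    },
    "PIMA": {
        "SpikeProp": 78.6, "SWAT": 77.0, "SRESN": 70.5, "TMM-SNN": 79.7,
        "GE-SNN": 79.0, "ANN": 78.4, "C-STNet": 78.2, "P-STNet": 78.5,
    },
    "Iris": {
        "SpikeProp": 97.2, "SWAT": 96.7, "SRESN": 96.9, "TMM-SNN": 97.5,
        "GE-SNN": 99.2, "ANN": 97.7, "C-STNet": 97.7, "P-STNet": 98.0,
    },
    "Wine": {
        "SpikeProp": 99.2, "SWAT": 98.6, "SRESN": 96.9, "TMM-SNN": 100.0,
        "GE-SNN": 96.4, "ANN": 99.9, "C-STNet": 99.9, "P-STNet": 99.9,
    },
}

#: printed Sonar test accuracies (only four approaches report it)
PUBLISHED_SONAR_TEST_ACCURACY: dict[str, float] = {
    "SpikeProp": 80.1, "ANN": 84.6, "C-STNet": 84.3, "P-STNet": 84.9,
}

#: printed average ranks over the five datasets above
PUBLISHED_AVERAGE_RANK: dict[str, float] = {
    "SpikeProp": 4.8, "SWAT": 7.2, "SRESN": 5.6, "TMM-SNN": 3.0,
    "GE-SNN": 6.6, "ANN": 3.2, "C-STNet": 2.8, "P-STNet": 1.6,
}
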