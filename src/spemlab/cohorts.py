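"""Published cohort-level inputs used as simulation parameters and fixtures.

Two kinds of published numbers are encoded here:

* Group-wise means/SDs of the four pursuit measures for each study cohort
  (training cohort B-SNIP1; external cohorts B-SNIP2, PARDIP, FOR2107,
  PRONIA), used to parameterise the cohort feature simulator, together
  with the training cohort's per-measure missingness rates.
* The confusion counts behind every reported classification result
  (three internal-validation folds plus the external cohorts), used as
  worked examples for the metric arithmetic.

Feature keys: ``gain_pred`` (predictive maintenance gain, ratio),
``gain_early`` (early maintenance gain, ratio), ``accel`` (initial eye
acceleration, deg/s^2), ``latency`` (ms).
"""

from __future__ import annotations

from .metrics import ConfusionCounts
from .simulate import CohortSpec, GroupSpec

__all__ = [
    "TABLE_SPEM",
    "MISSING_RATES_BSNIP1",
    "CONFUSION_COUNTS",
    "GROUP_PREDICTION_COUNTS",
    "cohort_spec",
    "bsnip1_spec",
]

CONTROL = "control"
PSYCHOSIS = "psychosis"


def _row(mean_gp, sd_gp, mean_ge, sd_ge, mean_ac, sd_ac, mean_lat, sd_lat):
    return (
        {"gain_pred": mean_gp, "gain_early": mean_ge, "accel": mean_ac, "latency": mean_lat},
        {"gain_pred": sd_gp, "gain_early": sd_ge, "accel": sd_ac, "latency": sd_lat},
    )


# study -> group name -> (n, means, sds, binary label)
TABLE_SPEM: dict[str, dict[str, tuple[int, dict, dict, str]]] = {
    "bsnip1": {
        "controls": (305, *_row(0.93, 0.10, 0.79, 0.19, 80.28, 35.49, 175.84, 26.59), CONTROL),
        "psychosis": (674, *_row(0.86, 0.17, 0.64, 0.25, 61.54, 34.52, 183.75, 37.23), PSYCHOSIS),
        "SZ": (265, *_row(0.84, 0.19, 0.62, 0.26, 60.30, 37.23, 182.01, 40.01), PSYCHOSIS),
        "SAD": (178, *_row(0.88, 0.15, 0.66, 0.24, 63.13, 34.00, 188.90, 38.00), PSYCHOSIS),
        "BP": (231, *_row(0.86, 0.17, 0.67, 0.24, 61.76, 31.66, 181.80, 32.88), PSYCHOSIS),
    },
    "bsnip2": {
        "controls": (292, *_row(0.93, 0.05, 0.76, 0.15, 80.99, 30.62, 180.01, 30.61), CONTROL),
        "psychosis": (727, *_row(0.85, 0.13, 0.59, 0.21, 72.91, 37.84, 196.18, 43.33), PSYCHOSIS),
    },
    "pardip": {
        "controls": (71, *_row(0.91, 0.11, 0.76, 0.18, 75.85, 31.93, 184.94, 32.66), CONTROL),
        "BPwP": (49, *_row(0.81, 0.16, 0.58, 0.22, 57.32, 30.82, 191.13, 49.20), PSYCHOSIS),
        "BPwoP": (36, *_row(0.87, 0.14, 0.70, 0.19, 65.52, 29.23, 188.25, 43.69), CONTROL),
    },
    "for2107": {
        "controls": (72, *_row(0.90, 0.08, 0.72, 0.17, 97.87, 32.79, 164.46, 15.94), CONTROL),
        "psychosis": (51, *_row(0.85, 0.15, 0.61, 0.18, 83.07, 29.07, 164.53, 16.73), PSYCHOSIS),
        "MDwoP": (94, *_row(0.90, 0.09, 0.72, 0.15, 103.92, 34.00, 162.56, 14.65), CONTROL),
        "BPwoP": (25, *_row(0.87, 0.10, 0.65, 0.15, 82.08, 28.40, 168.91, 15.51), CONTROL),
    },
    "pronia": {
        "controls": (16, *_row(0.91, 0.06, 0.77, 0.10, 107.79, 24.08, 165.36, 18.66), CONTROL),
        "ROD": (17, *_row(0.89, 0.10, 0.70, 0.19, 114.32, 42.53, 169.19, 21.96), CONTROL),
        "CHR": (19, *_row(0.81, 0.22, 0.60, 0.22, 99.46, 34.92, 178.34, 17.49), CONTROL),
        "ROP": (11, *_row(0.90, 0.08, 0.67, 0.14, 114.23, 46.02, 168.59, 17.22), PSYCHOSIS),
    },
}

# training-cohort per-measure missing-value rates (proportions)
MISSING_RATES_BSNIP1 = {
    "gain_pred": 0.0,
    "gain_early": 0.0051,
    "accel": 0.0123,
    "latency": 0.0051,
}


def cohort_spec(
    study: str,
    groups: tuple[str, ...] | None = None,
    missing_rates: dict[str, float] | None = None,
) -> CohortSpec:
    """Build a simulator :class:`CohortSpec` from a study's published rows.

    By default the two headline groups (controls + pooled psychosis when
    present, else all groups) are included; subgroup names select specific
    rows, e.g. ``cohort_spec("bsnip1", ("SZ", "SAD"))``.
    """
    table = TABLE_SPEM[study]
    if groups is None:
        groups = tuple(g for g in ("controls", "psychosis") if g in table) or tuple(table)
    specs = []
    for g in groups:
        n, means, sds, label = table[g]
        specs.append(GroupSpec(name=g, n=n, means=means, sds=sds, label=label))
    return CohortSpec(groups=tuple(specs), missing_rates=missing_rates or {})


def bsnip1_spec(with_missing: bool = True) -> CohortSpec:
    """Training-cohort spec: 305 controls vs 674 psychosis probands."""
    return cohort_spec(
        "bsnip1",
        ("controls", "psychosis"),
        MISSING_RATES_BSNIP1 if with_missing else None,
    )


# Confusion counts behind every reported accuracy (positive class = psychosis).
CONFUSION_COUNTS: dict[str, ConfusionCounts] = {
    "bsnip1_fold1": ConfusionCounts(tp=122, fn=101, tn=72, fp=32),
    "bsnip1_fold2": ConfusionCounts(tp=124, fn=113, tn=67, fp=22),
    "bsnip1_fold3": ConfusionCounts(tp=111, fn=103, tn=90, fp=22),
    "bsnip2": ConfusionCounts(tp=373, fn=293, tn=214, fp=75),
    "pardip": ConfusionCounts(tp=30, fn=14, tn=44, fp=26),
    "for2107": ConfusionCounts(tp=22, fn=29, tn=53, fp=19),
}

# groups reported only as predicted-label counts (n_psychosis, n_control)
GROUP_PREDICTION_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "pardip": {"BPwoP": (13, 20)},
    "for2107": {"MDwoP": (18, 76), "BPwoP": (10, 15)},
    "pronia": {
        "controls": (1, 15),
        "ROD": (4, 13),
        "CHR": (8, 11),
        "ROP": (2, 9),
    },
}
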