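"""Published BRAF variant rosters and reported classification calls.

These small tables are the study inputs of the original BRAF REST2
ensemble analysis: the clinical drug-response roster of the simulated
variants (sensitive 'S', resistant 'R', or 'unknown' per drug), the
reported leave-one-variant-out calls for the variants with known status,
the reported calls for the variants of uncertain significance (VUS), and
the dihedral angles the published feature selection retained per drug.

They are used to seed realistic synthetic studies and to recompute the
published performance metrics from the variant-level calls.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "variant_roster",
    "known_calls",
    "vus_calls",
    "REPORTED_SELECTION_ROUNDS",
    "REPORTED_ACCURACY_PCT",
    "DRUGS",
]

DRUGS = ("dabrafenib", "vemurafenib")

# variant -> (dabrafenib status, vemurafenib status)
_ROSTER = {
    "V600E": ("S", "S"),
    "V600M": ("S", "S"),
    "V600K": ("S", "S"),
    "V600D": ("S", "S"),
    "V600R": ("S", "S"),
    "G466E": ("R", "R"),
    "WT": ("S", "unknown"),
    "L597S": ("S", "unknown"),
    "K601E": ("R", "unknown"),
    "G469A": ("R", "R"),
    "G469V": ("R", "unknown"),
    "S467L": ("R", "unknown"),
    "L505H": ("unknown", "R"),
    "L597R": ("unknown", "S"),
    "V600E+L505H": ("unknown", "R"),
    "V600E+L514V": ("unknown", "R"),
}

# variant -> (true status, reported model call), variants with known status
_KNOWN_CALLS = {
    "dabrafenib": {
        "V600E": ("S", "S"), "V600M": ("S", "S"), "V600K": ("S", "S"),
        "V600D": ("S", "S"), "V600R": ("S", "S"), "G466E": ("R", "R"),
        "WT": ("S", "S"), "L597S": ("S", "S"), "K601E": ("R", "S"),
        "G469A": ("R", "R"), "G469V": ("R", "R"), "S467L": ("R", "R"),
    },
    "vemurafenib": {
        "V600E": ("S", "S"), "V600M": ("S", "S"), "V600K": ("S", "S"),
        "V600D": ("S", "S"), "V600R": ("S", "S"), "L505H": ("R", "R"),
        "G466E": ("R", "R"), "G469A": ("R", "R"),
        "V600E+L514V": ("R", "R"), "L597R": ("S", "S"),
        "V600E+L505H": ("R", "R"),
    },
}

# reported calls for the variants of uncertain significance
_VUS_CALLS = {
    "dabrafenib": {
        "L505H": "S", "L597R": "R", "V600E+L505H": "R", "V600E+L514V": "S",
    },
    "vemurafenib": {
        "S467V": "S", "G469V": "R", "K601E": "R", "L597S": "S", "WT": "S",
    },
}

#: Angles retained by the published iterative decision-tree selection,
#: grouped by the selection round (tree) that found them.
REPORTED_SELECTION_ROUNDS = {
    "dabrafenib": [
        ["phi644", "phi600"],
        ["phi663", "psi494"],
        ["psi675", "phi677"],
    ],
    "vemurafenib": [
        ["psi622"],
        ["phi484"],
        ["psi450", "phi495"],
        ["phi518", "phi622"],
    ],
}

#: Reported variant-level leave-one-variant-out accuracy, percent.
REPORTED_ACCURACY_PCT = {"dabrafenib": 91.67, "vemurafenib": 100.0}


def variant_roster() -> pd.DataFrame:
    """Label table (variant, drug, status) for the 16 simulated variants."""
    rows = [
        {"variant": v, "drug": drug, "status": statuses[i]}
        for v, statuses in _ROSTER.items()
        for i, drug in enumerate(DRUGS)
    ]
    return pd.DataFrame(rows)


def known_calls(drug: str) -> pd.DataFrame:
    """Reported (truth, call) pairs for the known-status variants of a drug."""
    _check_drug(drug)
    return pd.DataFrame(
        [{"variant": v, "status": t, "prediction": p}
         for v, (t, p) in _KNOWN_CALLS[drug].items()]
    )


def vus_calls(drug: str) -> pd.DataFrame:
    """Reported calls for the variants of uncertain significance."""
    _check_drug(drug)
    return pd.DataFrame(
        [{"variant": v, "prediction": p} for v, p in _VUS_CALLS[drug].items()]
    )


def _check_drug(drug):
    if drug not in DRUGS:
        raise ValueError(f"unknown drug {drug!r}; expected one of {DRUGS}")
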