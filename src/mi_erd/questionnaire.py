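"""Embodiment/presence questionnaire scoring and condition comparison.

Sixteen embodiment items (E1-E16), five physical-presence items (P1-P5) and an
optional post-MI embodiment item (MIQ1), all on a 1-7 Likert scale, reduce to
seven composites plus Embodiment-MI:

    Appearance        = (E1+E2+E3+E4+E5+E6+E9+E16)/8
    Response          = (E4+E6+E7+E8+E9+E15)/6
    Ownership         = (E5+E10+E11+E12+E13+E14)/6
    Multi-sensory     = (E3+E12+E13+E14+E15+E16)/6
    Agency            = (E3+E13)/2
    Embodiment        = (Appearance+Response+Ownership+Multi-sensory)/4
    Physical Presence = (P1+P2+P3+P4+P5)/5
    Embodiment MI     = MIQ1

Items may legitimately contribute to several composites (e.g. E3 feeds
appearance, multi-sensory and agency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mann_whitney_u

__all__ = [
    "COMPOSITE_ITEMS",
    "FEATURE_NAMES",
    "QuestionnaireResponse",
    "EmbodimentFeatures",
    "score_embodiment",
    "score_dataframe",
    "compare_conditions",
]

COMPOSITE_ITEMS = {
    "appearance": ["E1", "E2", "E3", "E4", "E5", "E6", "E9", "E16"],
    "response": ["E4", "E6", "E7", "E8", "E9", "E15"],
    "ownership": ["E5", "E10", "E11", "E12", "E13", "E14"],
    "multi_sensory": ["E3", "E12", "E13", "E14", "E15", "E16"],
    "agency": ["E3", "E13"],
    "physical_presence": ["P1", "P2", "P3", "P4", "P5"],
}

FEATURE_NAMES = [
    "appearance", "response", "ownership", "multi_sensory", "agency",
    "embodiment", "physical_presence", "embodiment_mi",
]

_REQUIRED = [f"E{i}" for i in range(1, 17)] + [f"P{i}" for i in range(1, 6)]


@dataclass
class QuestionnaireResponse:
    """One subject x condition set of Likert item scores."""

    items: dict
    subject: str = ""
    condition: str = ""

    def __post_init__(self):
        for key in _REQUIRED:
            if key not in self.items:
                raise ValueError(f"missing questionnaire item {key}")
        for key, val in self.items.items():
            if key == "MIQ1" and val is None:
                continue
            if not float(val).is_integer() or not 1 <= int(val) <= 7:
                raise ValueError(f"item {key} must be an integer in [1, 7]; got {val!r}")


@dataclass
class EmbodimentFeatures:
    appearance: float
    response: float
    ownership: float
    multi_sensory: float
    agency: float
    embodiment: float
    physical_presence: float
    embodiment_mi: float = None
    subject: str = ""
    condition: str = ""

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def score_embodiment(resp: QuestionnaireResponse) -> EmbodimentFeatures:
    """Compute the seven composites (and Embodiment-MI when MIQ1 is present)."""
    items = resp.items
    vals = {name: float(np.mean([items[i] for i in keys]))
            for name, keys in COMPOSITE_ITEMS.items()}
    vals["embodiment"] = (
        vals["appearance"] + vals["response"] + vals["ownership"] + vals["multi_sensory"]
    ) / 4.0
    miq1 = items.get("MIQ1")
    return EmbodimentFeatures(
        **vals,
        embodiment_mi=float(miq1) if miq1 is not None else None,
        subject=resp.subject,
        condition=resp.condition,
    )


def score_dataframe(responses: pd.DataFrame) -> pd.DataFrame:
    """Score a tidy item table (one row per subject x condition) to features."""
    rows = []
    for _, row in responses.iterrows():
        items = {k: row[k] for k in _REQUIRED}
        if "MIQ1" in row and pd.notna(row.get("MIQ1")):
            items["MIQ1"] = row["MIQ1"]
        feats = score_embodiment(QuestionnaireResponse(
            items=items, subject=str(row.get("subject", "")),
            condition=str(row.get("condition", "")),
        ))
        out = {"subject": feats.subject, "condition": feats.condition}
        out.update(feats.as_dict())
        rows.append(out)
    return pd.DataFrame(rows)


def compare_conditions(features_a: pd.DataFrame, features_b: pd.DataFrame,
                       label_a: str = "Control", label_b: str = "Embodied",
                       u_convention: str = "first") -> pd.DataFrame:
    """Per-feature condition comparison (means +- SD, Mann-Whitney U, p).

    Inputs are per-subject feature tables as returned by
    :func:`score_dataframe` (one per condition). Features absent from either
    table (e.g. embodiment_mi in the pilot protocol) are skipped.
    """
    if len(features_a) == 0 or len(features_b) == 0:
        raise ValueError("both condition groups must be non-empty")
    rows = []
    for feature in FEATURE_NAMES:
        if feature not in features_a or feature not in features_b:
            continue
        a = features_a[feature].dropna().to_numpy(dtype=float)
        b = features_b[feature].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            continue
        res = mann_whitney_u(a, b, convention=u_convention)
        rows.append({
            "feature": feature,
            f"mean_{label_a}": a.mean(), f"sd_{label_a}": a.std(ddof=1) if a.size > 1 else 0.0,
            f"mean_{label_b}": b.mean(), f"sd_{label_b}": b.std(ddof=1) if b.size > 1 else 0.0,
            "U": res.statistic, "p_value": res.p_value,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)
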