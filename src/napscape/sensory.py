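"""Caregiver-reported sensory reactivity scoring (SP-2-style composite).

The composite combines the 13 sensory-sensitivity and 11 sensation-avoidance
items (24 items total, 5-point scale, "not applicable" allowed).  Raw scores
run from 1 = almost always to 5 = almost never, so items are reverse-scored
(6 - raw) and averaged over the non-NA items; high scores mean greater
affective and behavioural reactivity.  No respondent is excluded by NA
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError, ValidationError
from .io import ITEM_COLUMNS, N_ITEMS

N_SENSITIVITY = 13
N_AVOIDANCE = 11
QUADRANTS = ("sensitivity",) * N_SENSITIVITY + ("avoidance",) * N_AVOIDANCE

#: optional classification bands on the composite
MORE_REACTIVE_CUTOFF = 1.9
MUCH_MORE_REACTIVE_CUTOFF = 2.5


@dataclass
class QuestionnaireResponse:
    subject: str
    items: np.ndarray  # 24 values in {1..5} or NaN
    quadrants: tuple[str, ...] = QUADRANTS

    def __post_init__(self):
        self.items = np.asarray(self.items, dtype=float)
        if self.items.shape != (N_ITEMS,):
            raise ValidationError(f"expected {N_ITEMS} items, got {self.items.shape}")
        vals = self.items[~np.isnan(self.items)]
        if ((vals < 1) | (vals > 5)).any():
            raise ValidationError("item values must be in 1..5 or NA")


def score_reactivity(resp: QuestionnaireResponse) -> tuple[float, int]:
    """Composite reactivity score and the number of NA items.

    Reverse-scores each answered item (6 - raw) and averages; NA items are
    dropped without excluding the respondent.
    """
    na = int(np.isnan(resp.items).sum())
    answered = resp.items[~np.isnan(resp.items)]
    if answered.size == 0:
        raise InsufficientDataError(f"subject {resp.subject}: all items NA")
    return float(np.mean(6.0 - answered)), na


def classify_reactivity(score: float) -> str:
    if score > MUCH_MORE_REACTIVE_CUTOFF:
        return "much more reactive"
    if score > MORE_REACTIVE_CUTOFF:
        return "more reactive"
    return "typical"


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha with listwise deletion of rows containing NA.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total score)).
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ParameterError("need a subjects x items matrix with >= 2 items")
    m = m[~np.isnan(m).any(axis=1)]
    if m.shape[0] < 3:
        raise ParameterError("need >= 3 complete subjects")
    k = m.shape[1]
    item_var = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ParameterError("total score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))


def score_questionnaires(df: pd.DataFrame) -> pd.DataFrame:
    """Score a questionnaire table (one row per subject, I01..I24 columns).

    Returns subject, reactivity, n_na and the classification label.
    """
    rows = []
    for _, r in df.iterrows():
        resp = QuestionnaireResponse(str(r["subject"]), r[ITEM_COLUMNS].to_numpy(float))
        score, na = score_reactivity(resp)
        rows.append(
            {
                "subject": resp.subject,
                "reactivity": score,
                "n_na": na,
                "label": classify_reactivity(score),
            }
        )
    return pd.DataFrame(rows)
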