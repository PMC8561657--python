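"""Qualitative validation battery: growth on 36 carbon sources and
essentiality of 10 vitamins, scored by accuracy and the Matthews
correlation coefficient.

A substrate supports growth ("+") iff sole-carbon-source FBA yields a
growth rate above the call threshold; a vitamin is non-essential ("+") iff
growth persists with its uptake closed.  The in-silico call threshold
(1e-4 /h) is this package's documented choice — the wet-lab criterion was
pressure accumulation, for which no flux equivalent is printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .core.build import (
    CARBON_SOURCE_EXCHANGES,
    VITAMIN_EXCHANGES,
    set_sole_carbon_source,
)
from .core.model import MetabolicModel, ModelError
from .datasets import validation_battery
from .lp import fba

#: growth call threshold, 1/h
GROWTH_THRESHOLD = 1e-4


@dataclass(frozen=True)
class UtilizationTest:
    """One validation row: observed and predicted binary outcome."""

    substrate: str
    test_type: str  # "carbon" | "vitamin"
    experimental: str  # "+" | "-"
    predicted: str  # "+" | "-"

    def __post_init__(self) -> None:
        if self.test_type not in ("carbon", "vitamin"):
            raise ModelError(f"bad test_type {self.test_type!r}")
        for v in (self.experimental, self.predicted):
            if v not in ("+", "-"):
                raise ModelError(f"outcomes must be '+'/'-', got {v!r}")

    @property
    def correct(self) -> bool:
        return self.experimental == self.predicted


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def mcc(self) -> float:
        """Matthews correlation coefficient; defined as 0 when any marginal
        is empty."""
        denom = ((self.tp + self.fp) * (self.tp + self.fn)
                 * (self.tn + self.fp) * (self.tn + self.fn))
        if denom == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / math.sqrt(denom)


def predict_carbon_growth(
    model: MetabolicModel, substrate: str, uptake_limit: float = 1.5
) -> str:
    """Sole-carbon-source growth call ("+"/"-") for one substrate."""
    test_model = set_sole_carbon_source(model, substrate, uptake_limit)
    sol = fba(test_model)
    mu = sol.objective_value if sol.optimal else 0.0
    return "+" if (mu or 0.0) > GROWTH_THRESHOLD else "-"


def predict_vitamin_essentiality(model: MetabolicModel, vitamin: str) -> str:
    """"+" iff the model still grows with the vitamin's uptake closed."""
    key = vitamin.strip().lower()
    exchange_id = VITAMIN_EXCHANGES.get(key)
    if exchange_id is None:
        raise ModelError(f"unknown vitamin {vitamin!r}")
    test_model = model.copy()
    test_model.set_bounds(
        exchange_id, 0.0, test_model.reactions[exchange_id].upper_bound
    )
    sol = fba(test_model)
    mu = sol.objective_value if sol.optimal else 0.0
    return "+" if (mu or 0.0) > GROWTH_THRESHOLD else "-"


def run_battery(
    model: MetabolicModel,
    battery: Optional[pd.DataFrame] = None,
    uptake_limit: float = 1.5,
) -> List[UtilizationTest]:
    """Run every test of the packaged battery through the model."""
    battery = battery if battery is not None else validation_battery()
    tests: List[UtilizationTest] = []
    for _, row in battery.iterrows():
        if row["test_type"] == "carbon":
            call = predict_carbon_growth(model, row["substrate"], uptake_limit)
        else:
            call = predict_vitamin_essentiality(model, row["substrate"])
        tests.append(
            UtilizationTest(
                substrate=row["substrate"],
                test_type=row["test_type"],
                experimental=row["experimental"],
                predicted=call,
            )
        )
    return tests


def score_predictions(
    tests: Iterable[UtilizationTest],
) -> Tuple[float, float, ConfusionMatrix]:
    """(accuracy, MCC, confusion matrix), treating experimental growth as
    the positive class truth."""
    tp = fp = fn = tn = 0
    for t in tests:
        if t.experimental == "+" and t.predicted == "+":
            tp += 1
        elif t.experimental == "-" and t.predicted == "+":
            fp += 1
        elif t.experimental == "+" and t.predicted == "-":
            fn += 1
        else:
            tn += 1
    cm = ConfusionMatrix(tp, fp, fn, tn)
    return cm.accuracy, cm.mcc, cm


def battery_frame(tests: Iterable[UtilizationTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "substrate": t.substrate,
                "test_type": t.test_type,
                "experimental": t.experimental,
                "predicted": t.predicted,
                "correct": t.correct,
            }
            for t in tests
        ]
    )
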