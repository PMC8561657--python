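"""Packaged measured datasets: macromolecular composition, the
substrate/vitamin validation battery, and the measured extracellular fluxes
of *N. lanati* growing on cellobiose (mmol/gDW/h)."""

from __future__ import annotations

from importlib import resources
from typing import List

import pandas as pd

from .lp import MeasuredFlux

#: metabolite stems behind the measured-flux table
MEASURED_PRODUCT_STEMS = {
    "succinate": "succ",
    "lactate": "lac__L",
    "ethanol": "etoh",
    "formate": "for",
    "acetate": "ac",
    "h2": "h2",
}


def _data_path(name: str):
    return resources.files("hydrogem.data").joinpath(name)


def load_table(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, sep="\t")


def composition_table() -> pd.DataFrame:
    """Measured macromolecular mass fractions (percent of dry weight)."""
    return load_table("table2.tsv")


def validation_battery() -> pd.DataFrame:
    """The 46 substrate-utilization / vitamin-essentiality tests with the
    printed model-prediction and experimental-outcome columns."""
    df = load_table("table4.tsv")
    assert len(df) == 46
    return df


def measured_fluxes() -> List[MeasuredFlux]:
    """Measured exponential-phase secretion rates as bound intervals."""
    df = load_table("table5.tsv")
    out = []
    for _, row in df.iterrows():
        out.append(
            MeasuredFlux(
                product=MEASURED_PRODUCT_STEMS[row["metabolite"]],
                mean=float(row["mean"]),
                sd=float(row["sd"]),
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
            )
        )
    return out


def measured_flux_frame() -> pd.DataFrame:
    return load_table("table5.tsv")
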