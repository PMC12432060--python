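"""Loader for the packaged reference annotation set.

The fixture is a curated table of 44 sulfated and non-sulfated phenolic
compounds annotated in edible and infesting seaweed extracts: retention
time, molecular formula, experimental neutral mass and [M-H]- m/z, mass
accuracy, diagnostic product ions and identification confidence level
(Schymanski scale).  It drives regression tests for the mass computations,
the classification counts and the MS2 rule engine, and provides realistic
templates for the synthetic-data generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_annotations", "reference_spectrum_peaks"]


def load_reference_annotations() -> pd.DataFrame:
    """Return the 44-compound reference table as a DataFrame.

    Columns: ``id, name, base_aglycone, n_sulfates, rt_min, formula,
    molecular_weight, experimental_mz, delta_ppm, diagnostic_ions,
    confidence_level``; ``diagnostic_ions`` is parsed into a list of floats.
    """
    path = resources.files("sulfoscreen").joinpath(
        "data/seaweed_reference_annotations.csv"
    )
    with resources.as_file(path) as fname:
        table = pd.read_csv(fname)
    table["diagnostic_ions"] = table["diagnostic_ions"].map(
        lambda ions: [float(x) for x in str(ions).split(";")]
    )
    return table


def reference_spectrum_peaks(row: pd.Series) -> list[tuple[float, float]]:
    """Assemble an equal-intensity centroid peak list from one fixture row.

    Intensities carry no information in the curated table, so every
    diagnostic ion is emitted at intensity 100 (well above any relative
    intensity threshold).
    """
    return [(mz, 100.0) for mz in sorted(row["diagnostic_ions"])]
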