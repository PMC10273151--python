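"""Shipped reference data.

``indeterminate12.csv`` is the published worked example this package
uses as its threshold oracle: twelve specimens whose intraoperative
frozen-section diagnosis was indeterminate, with the spectral
infiltration index printed for each and the final paraffin-pathology
grade as ground truth.  At the strict operating threshold (index > 4.5)
the spectral call agrees with paraffin on 9 of 12, and all three errors
are underestimates (invasive lesions called non-invasive).
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from ..data import FSCall, SpectralClass

__all__ = ["load_indeterminate_cases"]


def load_indeterminate_cases() -> pd.DataFrame:
    """The 12-case FS-indeterminate worked example.

    Columns: case (int), truth (SpectralClass name), infiltration_index
    (float, one decimal), fs_call (always INDETERMINATE).
    """
    ref = importlib.resources.files(__package__) / "indeterminate12.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df["truth"] = df["truth"].map(SpectralClass)
    df["fs_call"] = df["fs_call"].map(FSCall)
    return df
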