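"""Packaged reference fixtures.

* the input and optimized PLFA ratio matrices for the nine pond taxa
  (three fungal phyla, three bacterial phyla, green algae, cyanobacteria,
  diatoms), referenced to 16:0 = 1;
* the biomarker assignment table (FA → taxa it indicates);
* the default trophic marker scheme (fungi / bacteria / autotroph rules).

The printed source table is typographically ambiguous for the iso- and
anteiso-15:0 rows; the packaged CSVs assign those values to the bacterial
phyla (Actinobacteria, Firmicutes, Proteobacteria), the only taxa that
carry branched FA.  The CSVs are plain text and easy to amend if a better
reading emerges.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .profiles import TaxonRatioMatrix

__all__ = [
    "load_ratio_matrix_input",
    "load_ratio_matrix_output",
    "load_marker_table",
    "data_path",
]


def data_path(name: str):
    """Path-like handle to a packaged data file."""
    return resources.files("plfatax.data") / name


def load_ratio_matrix_input() -> TaxonRatioMatrix:
    """The nine-taxon PLFA ratio matrix used as unmixing input (R0)."""
    with resources.as_file(data_path("table3_input.csv")) as p:
        return TaxonRatioMatrix.from_csv(p, provenance="packaged ratio matrix (input)")


def load_ratio_matrix_output() -> TaxonRatioMatrix:
    """The corresponding optimized ratio matrix reported by the source study."""
    with resources.as_file(data_path("table3_output.csv")) as p:
        return TaxonRatioMatrix.from_csv(p, provenance="packaged ratio matrix (output)")


def load_marker_table() -> pd.DataFrame:
    """Biomarker table: FA name, structural category, taxa it marks."""
    with resources.as_file(data_path("table1_markers.csv")) as p:
        return pd.read_csv(p)
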