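"""Packaged datasets.

The per-patient score/EVLW table of the validation study (12 ICU patients
with acute respiratory distress, five lung-ultrasound scores each, plus
extravascular lung water from transpulmonary thermo-dilution in mL/kg) ships
with the package so the statistical validation runs fully offline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Score columns of the validation table, in reporting order.
SCORE_COLUMNS = ("QLUSS", "cLUSS", "qLUSS", "%LUSS", "nLUSS")


def table1_path() -> str:
    """Filesystem path of the packaged per-patient score/EVLW table."""
    return str(resources.files("qluss.data").joinpath("table1.csv"))


def load_table1() -> pd.DataFrame:
    """Load the per-patient score/EVLW validation table.

    Columns: ``Patients`` (1-12), the five scores (``QLUSS`` in percent,
    ``qLUSS``/``cLUSS`` on the summed 0-36 grade scales, ``%LUSS`` in
    B-line-equivalents, ``nLUSS`` a count) and ``EVLW`` in mL/kg.
    """
    with resources.files("qluss.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)
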