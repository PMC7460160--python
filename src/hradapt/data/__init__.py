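"""Packaged worked-example data.

``pilot_paired_rows.csv`` (n = 3 laboratory crossover) and
``field_paired_rows.csv`` (n = 29 kindergarten crossover) hold the published
paired-test summary rows — mean and SD of the UAS−CIS differences per
scenario-level variable, with the printed SE, 95% CI, t, df and p for
cross-checking. The first three columns fully determine the rest; the
evaluation pipeline recomputes them from those columns alone.
"""

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["published_paired_rows"]

_FILES = {"pilot": "pilot_paired_rows.csv", "field": "field_paired_rows.csv"}


def published_paired_rows(study: str = "pilot") -> pd.DataFrame:
    """Load the published paired-test rows for one study arm of the evaluation.

    ``study`` is ``"pilot"`` (n=3) or ``"field"`` (n=29).
    """
    try:
        fname = _FILES[study]
    except KeyError:
        raise ValueError(f"study must be one of {sorted(_FILES)}, got {study!r}")
    with resources.as_file(resources.files(__package__) / fname) as path:
        return pd.read_csv(Path(path))
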