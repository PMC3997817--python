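"""Bundled reference tables.

``load_call_summary`` returns the published per-strain CNV call summary of
the four-silkworm resequencing study (total span in bp, number of calls and
the printed average size in kb, before and after high-confidence filtering).
It is used to check the package's size arithmetic against the published
figures: ``avg_size_kb`` recomputes total_bp / n_calls / 1000.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_call_summary"]


def load_call_summary() -> pd.DataFrame:
    with resources.files("silkcnv.data").joinpath(
        "silkworm_call_summary.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["avg_size_kb"] = df["total_bp"] / df["n_calls"] / 1000.0
    return df
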