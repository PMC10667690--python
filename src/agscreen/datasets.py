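"""Small bundled datasets."""

from importlib import resources

import pandas as pd


def load_example_donor_table() -> pd.DataFrame:
    """Donor candidates from a published rice anaerobic-germination screening.

    Columns: genotype, condition (selection rule), selection_index,
    germ21_blup_pct and remarks (Entry/Check).  Useful for exercising the
    selection rules on realistic index/germination values.
    """
    path = resources.files("agscreen") / "data" / "example_donor_table.tsv"
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")
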