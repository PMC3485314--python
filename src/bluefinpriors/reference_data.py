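"""Bundled observed larval/juvenile mortality rates for comparison plots.

Field and rearing observations of instantaneous daily and cumulative
mortality rates for tunas and small pelagics, used only to sanity-check
the simulated rates against independent measurements — never as model
input.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_observed_mortality"]


def load_observed_mortality() -> pd.DataFrame:
    """Observed YOY mortality rates (columns: species, age_days,
    age_reference, kind, mortality, source)."""
    ref = resources.files("bluefinpriors.data") / "larval_mortality_observations.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
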