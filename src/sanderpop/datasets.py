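"""Small bundled datasets."""

from importlib import resources

import pandas as pd


def load_published_hybrids() -> pd.DataFrame:
    """The eight wild fish reported as genotypic hybrids in the Wind/Bighorn
    survey, with their published (q, Q) estimates, sampling location,
    field phenotype call and sex.

    Useful as a worked example for :func:`sanderpop.classify_hybrid`.
    """
    with resources.files("sanderpop.data").joinpath("published_hybrids.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
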