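"""Bundled example data.

``load_crc_verification_counts`` returns the per-SNP genotype count tables of
seven candidate colorectal-cancer SNPs genotyped individually in a Polish
case-control cohort (465 cases, ~1079 controls; per-SNP totals vary slightly
with missing calls).  They serve as the worked example for the
verification-stage statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .assoc import GenotypeCountTable

__all__ = ["load_crc_verification_counts", "load_crc_verification_frame"]


def load_crc_verification_frame() -> pd.DataFrame:
    """The bundled count tables as a raw data frame."""
    with resources.files("poolgwas.data").joinpath(
        "crc_verification_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_crc_verification_counts() -> list[GenotypeCountTable]:
    """The bundled count tables as :class:`GenotypeCountTable` records."""
    df = load_crc_verification_frame()
    return [
        GenotypeCountTable(
            snp_id=r.snp_id,
            case_mm=int(r.case_mm), case_mM=int(r.case_mM), case_MM=int(r.case_MM),
            ctrl_mm=int(r.ctrl_mm), ctrl_mM=int(r.ctrl_mM), ctrl_MM=int(r.ctrl_MM),
            minor_allele=r.minor_allele, major_allele=r.major_allele,
            region=r.region,
        )
        for r in df.itertuples(index=False)
    ]
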