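"""Packaged reference datasets.

``load_igg3_table`` returns the published per-allele REES fit summary
for the 21 IgG3 antibody variants: triplicate-average CSM(lambda_Ex,FC)
and Delta G_m with standard deviations, the group-shared relaxed-state
CSM, and the average SASA per Trp from homology models.  The 18
IgG3-Arg292 alleles carry 22 tryptophans per molecule; the three
IgG3-Trp292 alleles carry 24 (the Arg292Trp polymorphism adds one
exposed Trp per heavy chain of the homodimer).

Note: Delta G_m values are stored as printed (the published unit label
is mJ mol^-1 nm^-1); they are used as summary numbers, not re-entered
into the Boltzmann exponent.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import CorrelationResult, pearson

__all__ = ["load_igg3_table", "group_parameter_means", "sasa_correlations"]

ARG292 = "IgG3-Arg292"
TRP292 = "IgG3-Trp292"


def load_igg3_table() -> pd.DataFrame:
    """Per-allele REES parameters and SASA per Trp (21 IgG3 alleles)."""
    with resources.files("reesfit.data").joinpath("table1_igg3.csv").open() as fh:
        return pd.read_csv(fh)


def group_parameter_means(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group means (mean of per-allele triplicate averages) and sds.

    One row per group with csm_fc, dgm and sasa_per_trp means; matches
    the bottom section of the published parameter table.
    """
    if table is None:
        table = load_igg3_table()
    agg = table.groupby("group").agg(
        n_alleles=("allele", "count"),
        csm_fc_mean=("csm_fc_avg", "mean"),
        csm_fc_sd=("csm_fc_avg", lambda v: v.std(ddof=1)),
        dgm_mean=("dgm_avg", "mean"),
        dgm_sd=("dgm_avg", lambda v: v.std(ddof=1)),
        csm_r=("csm_r_avg", "first"),
        sasa_per_trp_mean=("sasa_per_trp", "mean"),
        sasa_per_trp_sd=("sasa_per_trp", lambda v: v.std(ddof=1)),
    )
    return agg


def sasa_correlations(
    table: pd.DataFrame | None = None,
) -> dict[str, CorrelationResult]:
    """Pearson correlations of REES parameters vs average SASA per Trp.

    Computed on the 21 per-allele triplicate averages: CSM(lambda_Ex,FC)
    vs SASA per Trp and Delta G_m vs SASA per Trp.
    """
    if table is None:
        table = load_igg3_table()
    return {
        "csm_fc_vs_sasa": pearson(table["sasa_per_trp"], table["csm_fc_avg"]),
        "dgm_vs_sasa": pearson(table["sasa_per_trp"], table["dgm_avg"]),
    }
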