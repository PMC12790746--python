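"""Allele-specific expression and X-inactivation status calling.

At heterozygous transcribed SNPs on X-linked genes, intact X inactivation
yields monoallelic expression (essentially all reads from the active X),
while escape from inactivation — or erosion of the inactive X — yields
biallelic expression. A SNP is *informative* when its read coverage is at
least ``min_snp_coverage`` (boundary inclusive). Classification uses the
major-allele fraction f = max(A, B) / (A + B):

* f >= mono_threshold      -> monoallelic
* f <= biallelic_threshold -> biallelic
* otherwise                -> ambiguous

Multiple SNPs in one gene are classified per SNP (phase-free) and combined
by majority vote; ties give ambiguous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError

__all__ = ["call_xci_status", "aggregate_line_xci"]

_STATUSES = ("monoallelic", "biallelic", "ambiguous", "uninformative")


def _classify(major_frac: float, mono: float, biallelic: float) -> str:
    if major_frac >= mono:
        return "monoallelic"
    if major_frac <= biallelic:
        return "biallelic"
    return "ambiguous"


def call_xci_status(allele_counts: pd.DataFrame, min_snp_coverage: int = 10,
                    mono_threshold: float = 0.95,
                    biallelic_threshold: float = 0.80,
                    binomial_test: bool = False) -> pd.DataFrame:
    """Per (gene, sample) X-inactivation status from allele counts.

    Returns one row per gene/sample pair with the number of informative
    SNPs, the summed coverage, the aggregate major-allele fraction
    (major/minor summed per SNP, so the value is polarity-free), and the
    voted status. With ``binomial_test=True``, an exact two-sided binomial
    p value against allelic balance (p = 0.5) on the aggregate counts is
    added.
    """
    if biallelic_threshold >= mono_threshold:
        raise InputError("biallelic_threshold must be < mono_threshold")
    if min_snp_coverage < 0:
        raise InputError("min_snp_coverage must be >= 0")
    tab = allele_counts.copy()
    if ((tab["count_allele_A"] < 0) | (tab["count_allele_B"] < 0)).any():
        raise InputError("allele counts must be nonnegative")

    tab["coverage"] = tab["count_allele_A"] + tab["count_allele_B"]
    tab["major"] = tab[["count_allele_A", "count_allele_B"]].max(axis=1)
    tab["minor"] = tab[["count_allele_A", "count_allele_B"]].min(axis=1)
    tab["informative"] = tab["coverage"] >= min_snp_coverage

    records = []
    for (gene, sample), grp in tab.groupby(["gene_id", "sample_id"], sort=True):
        inf = grp[grp["informative"]]
        if inf.empty:
            records.append((gene, sample, 0, int(grp["coverage"].sum()),
                            np.nan, "uninformative"))
            continue
        votes = [_classify(row.major / row.coverage, mono_threshold,
                           biallelic_threshold)
                 for row in inf.itertuples()]
        counts = pd.Series(votes).value_counts()
        top = counts[counts == counts.max()]
        status = top.index[0] if len(top) == 1 else "ambiguous"
        major_sum = int(inf["major"].sum())
        cov_sum = int(inf["coverage"].sum())
        records.append((gene, sample, len(inf), cov_sum,
                        major_sum / cov_sum, status))
    calls = pd.DataFrame(records, columns=[
        "gene_id", "sample_id", "n_informative_snps", "coverage",
        "major_allele_fraction", "status"])

    if binomial_test:
        pvals = []
        for row in calls.itertuples():
            if row.status == "uninformative" or row.coverage == 0:
                pvals.append(np.nan)
            else:
                k = int(round(row.major_allele_fraction * row.coverage))
                pvals.append(stats.binomtest(k, row.coverage, 0.5).pvalue)
        calls["p_binom"] = pvals
    return calls


def aggregate_line_xci(calls: pd.DataFrame, annotation: pd.DataFrame,
                       erosion_biallelic_cutoff: float = 0.2) -> pd.DataFrame:
    """Per-sample XCI summary, split by X-gene category.

    Counts monoallelic/biallelic/ambiguous calls separately among XCI-subject
    genes and among escapees, and raises an erosion flag when the biallelic
    fraction among *informative XCI-subject* genes exceeds the cutoff
    (default 0.2). Samples without informative XCI-subject genes get a NaN
    fraction and no flag.
    """
    cat = annotation.set_index("gene_id")["x_category"]
    merged = calls.assign(x_category=calls["gene_id"].map(cat))

    records = []
    for sample, grp in merged.groupby("sample_id", sort=True):
        rec: dict = {"sample_id": sample}
        for label, sub in (("xci_subject", grp[grp["x_category"] == "xci_subject"]),
                           ("escapee", grp[grp["x_category"] == "escapee"])):
            informative = sub[sub["status"] != "uninformative"]
            for st in ("monoallelic", "biallelic", "ambiguous"):
                rec[f"{label}_{st}"] = int((informative["status"] == st).sum())
            rec[f"{label}_informative"] = len(informative)
        n_inf = rec["xci_subject_informative"]
        if n_inf > 0:
            frac = rec["xci_subject_biallelic"] / n_inf
            rec["xci_subject_biallelic_fraction"] = frac
            rec["erosion_flag"] = bool(frac > erosion_biallelic_cutoff)
        else:
            rec["xci_subject_biallelic_fraction"] = np.nan
            rec["erosion_flag"] = False
        records.append(rec)
    return pd.DataFrame(records)
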