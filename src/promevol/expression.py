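"""Expression divergence between species and between hybrid alleles.

TPM normalisation, per-gene log2 fold changes, significance rules for
divergent expression, hybrid allele filtering (X-chromosome exclusion and
a minimum-detected-samples rule against inherited mono-allelic
expression), divergence fractions per gene group with chi-squared / BH
testing, enrichment of large fold changes across promoter-score (d)
tertiles, RT-PCR band densitometry, and the hybrid-vs-non-hybrid fold
change normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hotspots import compare_groups_chi2

#: significance presets: (minimum |log2FC| with inclusive/strict flag, max adj p)
PRESETS = {
    # fold-change-only rule used for tertile enrichment: |log2FC| > 1, strict
    "large_change": {"lfc_min": 1.0, "strict": True, "p_max": None},
    # divergent-expression rule: |log2FC| >= 0.5 and adjusted p <= 0.05
    "divergent": {"lfc_min": 0.5, "strict": False, "p_max": 0.05},
}


@dataclass(frozen=True)
class DERecord:
    gene: str
    log2fc: float
    adj_p: float | None = None


def tpm(counts: pd.DataFrame, gene_length: pd.Series) -> pd.DataFrame:
    """Transcripts per million from a gene x sample count matrix.

    Counts are divided by gene length in kb and each column rescaled to
    sum to 10^6. Gene lengths are in nucleotides.
    """
    lengths = gene_length.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise KeyError(f"genes without a length: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    return rate.div(totals, axis=1) * 1e6


def log2fc(tpm_a, tpm_b, pseudocount: float = 1.0) -> float:
    """log2((mean_a + pseudocount) / (mean_b + pseudocount)) across samples."""
    a = np.asarray(tpm_a, dtype=float)
    b = np.asarray(tpm_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("need at least one sample per side")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("expression values must be non-negative")
    return float(np.log2((a.mean() + pseudocount) / (b.mean() + pseudocount)))


def log2fc_table(tpm_a: pd.DataFrame, tpm_b: pd.DataFrame, pseudocount: float = 1.0) -> pd.Series:
    """Per-gene log2 fold change between two TPM matrices sharing genes."""
    genes = tpm_a.index.intersection(tpm_b.index)
    ma = tpm_a.loc[genes].mean(axis=1) + pseudocount
    mb = tpm_b.loc[genes].mean(axis=1) + pseudocount
    return np.log2(ma / mb)


def classify_de(record: DERecord, lfc_min: float = 0.5, p_max: float = 0.05,
                strict: bool = False) -> bool:
    """Divergent-expression call: |log2FC| >= lfc_min (or > if strict) and adj_p <= p_max.

    Missing adjusted p-values never qualify (the record is simply not
    significant). Set ``p_max=None`` for a fold-change-only rule.
    """
    big = abs(record.log2fc) > lfc_min if strict else abs(record.log2fc) >= lfc_min
    if p_max is None:
        return bool(big)
    if record.adj_p is None or (isinstance(record.adj_p, float) and np.isnan(record.adj_p)):
        return False
    return bool(big and record.adj_p <= p_max)


def welch_de_table(tpm_a: pd.DataFrame, tpm_b: pd.DataFrame,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Plain per-gene differential expression stand-in: Welch t on log-TPM, BH.

    A simple self-contained estimate of per-gene log2FC and adjusted p for
    runs without an externally fitted differential-expression table; not a
    moderated model.
    """
    genes = tpm_a.index.intersection(tpm_b.index)
    la = np.log2(tpm_a.loc[genes] + pseudocount)
    lb = np.log2(tpm_b.loc[genes] + pseudocount)
    t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": la.mean(axis=1) - lb.mean(axis=1), "adj_p": adj}, index=genes
    )


def hybrid_allele_filter(
    table: pd.DataFrame,
    min_samples: int = 4,
    exclude_chrom=("X",),
    gene_col: str = "gene",
    chrom_col: str = "chrom",
    allele_col: str = "allele",
) -> pd.DataFrame:
    """Filter a hybrid allele-count table (rows = gene x allele, count columns).

    Removes genes on excluded chromosomes and genes detected (nonzero) in
    fewer than ``min_samples`` of the pooled allele x replicate columns —
    the guard against mono-allelic expression inherited from one parent,
    such as X-linked genes carried only by one species.
    """
    if table.empty:
        raise ValueError("empty allele expression table")
    meta = [gene_col, chrom_col, allele_col]
    count_cols = [c for c in table.columns if c not in meta]
    per_gene = table.groupby(gene_col, sort=False)
    alleles = per_gene[allele_col].nunique()
    if (alleles != 2).any():
        bad = alleles.index[alleles != 2].tolist()[:5]
        raise ValueError(f"genes without exactly two alleles: {bad}")
    detected = (table[count_cols] > 0).groupby(table[gene_col], sort=False).sum().sum(axis=1)
    chrom = per_gene[chrom_col].first()
    keep = detected.index[(detected >= min_samples) & (~chrom.isin(exclude_chrom))]
    return table[table[gene_col].isin(keep)].reset_index(drop=True)


def divergence_fraction(
    groups: dict[str, list[str]],
    de: pd.DataFrame,
    control: str,
    lfc_min: float = 0.5,
    p_max: float = 0.05,
    strict: bool = False,
) -> pd.DataFrame:
    """Percent of divergently expressed genes per group, tested vs a control group.

    ``de`` is indexed by gene with columns log2fc and adj_p. Each
    non-control group is compared to the control with a 2x2 chi-squared
    test on significant vs not; p-values are Benjamini-Hochberg corrected
    across the family. Genes absent from ``de`` are dropped from a group.
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} not among groups")
    rows = {}
    for name, genes in groups.items():
        if not genes:
            raise ValueError(f"empty gene group {name!r}")
        present = [g for g in genes if g in de.index]
        if not present:
            raise ValueError(f"group {name!r} has no genes in the DE table")
        sub = de.loc[present]
        sig = [
            classify_de(DERecord(g, row["log2fc"], row.get("adj_p")),
                        lfc_min=lfc_min, p_max=p_max, strict=strict)
            for g, row in sub.iterrows()
        ]
        rows[name] = {"n_genes": len(present), "n_significant": int(np.sum(sig))}
    out = pd.DataFrame(rows).T
    out["pct_significant"] = 100.0 * out["n_significant"] / out["n_genes"]
    chi2s, ps = {}, {}
    others = [n for n in out.index if n != control]
    for name in others:
        chi2, p, _ = compare_groups_chi2(
            int(out.loc[name, "n_significant"]), int(out.loc[name, "n_genes"]),
            int(out.loc[control, "n_significant"]), int(out.loc[control, "n_genes"]),
        )
        chi2s[name], ps[name] = chi2, p
    out["chi2_vs_control"] = pd.Series(chi2s)
    out["p_raw"] = pd.Series(ps)
    if others:
        out.loc[others, "p_fdr"] = multipletests(out.loc[others, "p_raw"], method="fdr_bh")[1]
    return out


D_BINS = ((0.0, 100.0 / 3), (100.0 / 3, 200.0 / 3), (200.0 / 3, 100.0))


def tertile_enrichment(
    d_scores: pd.Series,
    lfc: pd.Series,
    bins=((0, 33), (33, 66), (66, 100)),
    lfc_abs: float = 1.0,
) -> pd.DataFrame:
    """Fraction of genes with |log2FC| > lfc_abs per promoter-score (d) tertile.

    Bins are (lo, hi] on d except the first, which includes d = 0. The
    fold-change rule is strict (> lfc_abs), per the large-change
    convention.
    """
    genes = d_scores.index.intersection(lfc.index)
    if len(genes) == 0:
        raise ValueError("no genes shared between d scores and fold changes")
    d = d_scores.loc[genes]
    if ((d < 0) | (d > 100)).any():
        raise ValueError("d scores must lie in [0, 100]")
    big = lfc.loc[genes].abs() > lfc_abs
    rows = []
    for lo, hi in bins:
        in_bin = (d > lo) & (d <= hi) if lo > 0 else (d >= lo) & (d <= hi)
        n = int(in_bin.sum())
        n_big = int((in_bin & big).sum())
        rows.append({
            "bin": f"({lo}, {hi}]" if lo > 0 else f"[{lo}, {hi}]",
            "n_genes": n,
            "n_changed": n_big,
            "pct_changed": 100.0 * n_big / n if n else np.nan,
        })
    return pd.DataFrame(rows).set_index("bin")


def distribution_shift_test(log2fc_a, log2fc_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else asymptotic."""
    a = np.asarray(log2fc_a, dtype=float)
    b = np.asarray(log2fc_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("need at least one value per side")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(u), float(p)


def densitometry_log2fc(ref_bands, other_bands) -> float:
    """Allele log2FC from gel band intensities.

    Each band is an (intensity, fragment_length_nt) pair; per-allele
    signal is the sum of intensity / fragment length over that allele's
    bands (digested fragments are length-normalised), and the result is
    log2(signal_ref / signal_other).
    """
    def signal(bands, side):
        bands = list(bands)
        if not bands:
            raise ValueError(f"no bands for the {side} allele")
        total = 0.0
        for intensity, length in bands:
            if intensity < 0 or length <= 0:
                raise ValueError("band intensities must be >= 0 and lengths > 0")
            total += intensity / length
        if total == 0:
            raise ValueError(f"zero total signal for the {side} allele")
        return total

    return float(np.log2(signal(ref_bands, "reference") / signal(other_bands, "other")))


def hybrid_vs_nonhybrid_ratio(log2fc_nonhybrid: float, log2fc_hybrid: float) -> float:
    """Hybrid allele log2FC normalised to the non-hybrid (species) log2FC.

    Computed as (1 / log2FC in non-hybrids) x log2FC in hybrids; 1 means
    the species difference is fully maintained between hybrid alleles.
    """
    if log2fc_nonhybrid == 0:
        raise ZeroDivisionError("non-hybrid log2FC of zero cannot be used as a reference")
    return log2fc_hybrid / log2fc_nonhybrid
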