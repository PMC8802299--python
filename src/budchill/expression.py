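"""qPCR relative-expression quantification (2^-ddCt) with QC and
reference-gene stability ranking.

The pipeline mirrors standard high-throughput qPCR practice: whole samples
or whole assays (gene/primer pairs) whose aggregate amplification quality
falls below a threshold are removed; candidate reference genes are ranked
for stability; relative expression is computed against one or more reference
genes and a single calibrator sample (whose relative expression is 1 by
definition); and per-gene trajectories are summarized per timepoint and
cultivar by two-stage (technical then biological) replicate averaging.

Ct tables are long-format pandas DataFrames with columns
``sample_id, date, cultivar, gene, bio_rep, tech_rep, ct, quality``.
Non-detected reactions carry NaN Ct and are treated as missing, never as
zero expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionError",
    "ExpressionProfileMatrix",
    "CT_COLUMNS",
    "qc_filter",
    "reference_stability",
    "delta_delta_ct",
    "summarize_profiles",
]

CT_COLUMNS = ["sample_id", "date", "cultivar", "gene", "bio_rep", "tech_rep", "ct", "quality"]


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionProfileMatrix:
    """Mean relative expression per gene x (timepoint, cultivar) cell.

    ``values`` is indexed by gene with a (date, cultivar) column MultiIndex;
    cells with zero surviving replicates are NaN (missing), never zero.
    ``counts`` holds the number of biological replicates behind each mean.
    """

    values: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values < 0).any().any():
            raise ExpressionError("negative relative expression in profile matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV-friendly export with ``date|cultivar`` column labels."""
        out = self.values.copy()
        out.columns = [f"{pd.Timestamp(d).date()}|{c}" for d, c in out.columns]
        out.index.name = "gene"
        return out


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ExpressionError(f"Ct table lacks columns {missing}")


def qc_filter(
    records: pd.DataFrame, threshold: float = 0.65
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop whole samples and whole assays with mean quality below threshold.

    Returns the surviving records and an exclusion log naming every removed
    unit (``unit_type`` in {sample, assay}, its id, mean quality, reason).
    Removal is unit-wise, mirroring plate QC practice where a failed primer
    pair or a failed sample invalidates all its reactions.
    """
    if not 0 <= threshold <= 1:
        raise ExpressionError("quality threshold must lie in [0, 1]")
    _check_columns(records)
    sample_q = records.groupby("sample_id")["quality"].mean()
    assay_q = records.groupby("gene")["quality"].mean()
    bad_samples = sample_q[sample_q < threshold]
    bad_assays = assay_q[assay_q < threshold]

    log_rows = [
        {
            "unit_type": "sample",
            "unit_id": sid,
            "mean_quality": q,
            "reason": f"mean quality {q:.3f} < {threshold}",
        }
        for sid, q in bad_samples.items()
    ] + [
        {
            "unit_type": "assay",
            "unit_id": gene,
            "mean_quality": q,
            "reason": f"mean quality {q:.3f} < {threshold}",
        }
        for gene, q in bad_assays.items()
    ]
    log = pd.DataFrame(log_rows, columns=["unit_type", "unit_id", "mean_quality", "reason"])

    kept = records[
        ~records["sample_id"].isin(bad_samples.index) & ~records["gene"].isin(bad_assays.index)
    ].copy()
    if kept.empty:
        raise ExpressionError("quality filter removed every record: unusable plate")
    return kept, log


def _tech_averaged_ct(records: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over technical replicates, one row per sample x gene."""
    return (
        records.groupby(["sample_id", "date", "cultivar", "bio_rep", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )


def reference_stability(
    records: pd.DataFrame,
    candidate_refs: list[str],
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Rank candidate reference genes by expression stability.

    Two component measures are computed on technical-replicate-averaged Ct:

    * ``m_value`` — geNorm-style stability: the mean, over all other
      candidates, of the standard deviation of the pairwise log2 expression
      ratio across samples (with perfect efficiency the log2 ratio is the Ct
      difference).
    * ``delta_ct_sd`` — comparative dCt stability: the mean SD of pairwise
      Ct differences, computed on the samples where both genes are detected.

    The comprehensive rank is the geometric mean of the per-measure ranks;
    lower means more stable.  Candidates missing in more than
    ``max_missing_frac`` of samples are excluded (reported with NaN
    measures and reason).
    """
    _check_columns(records)
    refs = list(dict.fromkeys(candidate_refs))
    if len(refs) < 2:
        raise ExpressionError("reference stability needs >= 2 candidate genes")
    sub = records[records["gene"].isin(refs)]
    tech = _tech_averaged_ct(sub)
    wide = tech.pivot_table(index="sample_id", columns="gene", values="ct", aggfunc="mean")
    n_samples = len(wide)
    usable, excluded = [], []
    for g in refs:
        if g not in wide.columns:
            excluded.append((g, "no Ct values"))
            continue
        frac_missing = wide[g].isna().sum() / n_samples
        if frac_missing > max_missing_frac:
            excluded.append((g, f"missing in {frac_missing:.0%} of samples"))
        else:
            usable.append(g)
    if len(usable) < 2:
        raise ExpressionError("fewer than 2 usable reference candidates after coverage check")

    m_values, dct_sds = {}, {}
    for g in usable:
        pair_sds = []
        for h in usable:
            if h == g:
                continue
            diff = (wide[g] - wide[h]).dropna()
            pair_sds.append(float(diff.std(ddof=1)) if len(diff) > 1 else np.nan)
        m_values[g] = float(np.nanmean(pair_sds))
        # With two-fold amplification the log2 ratio equals the Ct difference,
        # so both measures are computed from the same pairwise differences.
        dct_sds[g] = float(np.nanmean(pair_sds))

    table = pd.DataFrame(
        {
            "gene": usable,
            "m_value": [m_values[g] for g in usable],
            "delta_ct_sd": [dct_sds[g] for g in usable],
        }
    )
    table["rank_m"] = rankdata(table["m_value"])
    table["rank_delta_ct"] = rankdata(table["delta_ct_sd"])
    table["comprehensive_rank"] = np.sqrt(table["rank_m"] * table["rank_delta_ct"])
    table = table.sort_values("comprehensive_rank", ignore_index=True)
    for g, reason in excluded:
        table = pd.concat(
            [table, pd.DataFrame([{"gene": g, "reason_excluded": reason}])],
            ignore_index=True,
        )
    return table


def delta_delta_ct(
    records: pd.DataFrame,
    reference_genes: list[str],
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    Technical replicates are averaged first; per sample,
    ``dCt = Ct(target) - mean Ct(reference genes)``;
    ``ddCt = dCt(sample) - dCt(calibrator)``; ``rel_expr = 2^-ddCt``.
    Multiple reference genes are combined by the arithmetic mean of their Ct
    (the geometric mean of the linear quantities).  Non-detected targets stay
    missing.  The calibrator sample must carry a valid Ct for every gene.
    """
    _check_columns(records)
    refs = list(dict.fromkeys(reference_genes))
    if not refs:
        raise ExpressionError("at least one reference gene is required")
    tech = _tech_averaged_ct(records)
    genes = tech["gene"].unique()
    for r in refs:
        if r not in genes:
            raise ExpressionError(f"reference gene {r!r} absent from Ct table")

    ref_ct = (
        tech[tech["gene"].isin(refs)]
        .groupby("sample_id")["ct"]
        .mean()
        .rename("ref_ct")
    )
    targets = tech[~tech["gene"].isin(refs)].merge(ref_ct, on="sample_id", how="left")
    if targets["ref_ct"].isna().any():
        bad = targets.loc[targets["ref_ct"].isna(), "sample_id"].iloc[0]
        raise ExpressionError(f"sample {bad!r} lacks detected reference genes")
    targets["delta_ct"] = targets["ct"] - targets["ref_ct"]

    cal = targets[targets["sample_id"] == calibrator_sample]
    if cal.empty:
        raise ExpressionError(f"calibrator sample {calibrator_sample!r} absent from table")
    cal_dct = cal.set_index("gene")["delta_ct"]
    target_genes = [g for g in genes if g not in refs]
    for g in target_genes:
        if g not in cal_dct.index or pd.isna(cal_dct[g]):
            raise ExpressionError(
                f"calibrator sample {calibrator_sample!r} has no valid Ct for gene {g!r}"
            )

    targets["ddct"] = targets["delta_ct"] - targets["gene"].map(cal_dct)
    targets["rel_expr"] = np.power(2.0, -targets["ddct"])
    return targets[
        ["sample_id", "date", "cultivar", "bio_rep", "gene", "delta_ct", "ddct", "rel_expr"]
    ]


def summarize_profiles(rel: pd.DataFrame) -> ExpressionProfileMatrix:
    """Mean relative expression per (gene, date, cultivar).

    Averaging is two-stage: rows are first averaged within each biological
    replicate (so residual technical replicates never outweigh biological
    ones in unbalanced designs), then biological replicates are averaged per
    cell.  Cells where every replicate is missing stay NaN; biological
    replicate counts are recorded alongside.
    """
    needed = ["date", "cultivar", "gene", "bio_rep", "rel_expr"]
    missing = [c for c in needed if c not in rel.columns]
    if missing:
        raise ExpressionError(f"relative-expression table lacks columns {missing}")
    df = rel.copy()
    df["date"] = pd.to_datetime(df["date"])
    per_bio = (
        df.groupby(["gene", "date", "cultivar", "bio_rep"])["rel_expr"].mean().reset_index()
    )
    grouped = per_bio.groupby(["gene", "date", "cultivar"])["rel_expr"]
    means = grouped.mean().unstack(["date", "cultivar"]).sort_index(axis=1)
    counts = grouped.count().unstack(["date", "cultivar"]).reindex(columns=means.columns)
    counts = counts.fillna(0).astype(int)
    return ExpressionProfileMatrix(values=means, counts=counts)
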