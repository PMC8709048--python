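"""Counting, median-of-ratios normalization and log2FC expression tables.

Abundance is the raw number of full-length reads per variant and sample.
Sample size factors use the median-of-ratios (MRN) method: over variants
with all-positive counts, each sample's factor is the median of
count / (geometric mean across samples). Expression of each novel variant is
reported as log2FC against the pooled annotated transcripts of its gene:

    log2FC(v, s) = log2( (norm(v,s) + pc) / (sum_annotated norm(a,s) + pc) )

with pseudocount pc (default 0.5) guaranteeing finiteness.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .caller import CallResult, VariantCall
from .scanner import ReadEvidence

UNASSIGNED_ROW = "_unassigned"
DEFAULT_PSEUDOCOUNT = 0.5


class QuantError(ValueError):
    pass


def build_count_matrix(
    evidence: Sequence[ReadEvidence],
    calls: Sequence[VariantCall],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Variant x sample matrix of full-length supporting reads.

    Full-length resolvable reads whose structure matches no call are tallied
    in a ``_unassigned`` diagnostics row (excluded from normalization).
    """
    samples = list(samples)
    by_key = {c.structure.key: c.name for c in calls}
    index = [c.name for c in calls] + [UNASSIGNED_ROW]
    if len(set(index)) != len(index):
        raise QuantError("variant names are not unique")
    cm = pd.DataFrame(0, index=index, columns=samples, dtype=int)
    for ev in evidence:
        if ev.structure is None or not ev.full_length:
            continue
        if ev.sample not in cm.columns:
            raise QuantError(f"unknown sample tag {ev.sample!r}")
        cm.loc[by_key.get(ev.structure.key, UNASSIGNED_ROW), ev.sample] += 1
    for s in samples:
        if cm[s].sum() == 0:
            warnings.warn(f"sample {s!r} has zero full-length reads")
    return cm


def drop_diagnostics(cm: pd.DataFrame) -> pd.DataFrame:
    return cm.drop(index=[r for r in (UNASSIGNED_ROW,) if r in cm.index])


def mrn_size_factors(cm: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive real per sample).

    Only variants observed in every sample enter the geometric-mean
    reference (the standard MRN convention); with no such variant the
    factors are undefined and an error advises pooling or pseudocounts.
    """
    cm = drop_diagnostics(cm)
    positive = cm[(cm > 0).all(axis=1)]
    if positive.empty:
        raise QuantError(
            "no variant has positive counts in every sample; MRN size factors "
            "are undefined (consider pooling samples or adding a pseudocount)"
        )
    logs = np.log(positive.to_numpy(dtype=float))
    log_geomean = logs.mean(axis=1, keepdims=True)
    ratios = np.exp(logs - log_geomean)
    factors = pd.Series(np.median(ratios, axis=0), index=cm.columns, name="size_factor")
    return factors


def normalize(cm: pd.DataFrame, size_factors: Optional[pd.Series] = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = mrn_size_factors(cm)
    return drop_diagnostics(cm) / size_factors


def log2fc_table(
    cm_normalized: pd.DataFrame,
    calls: Sequence[VariantCall],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    denominator: str = "sum",
) -> pd.DataFrame:
    """Per novel variant and sample: log2 of its normalized abundance over
    the annotated transcripts of the same gene (``denominator='sum'`` pools
    all annotated variants; ``'max'`` uses the most abundant one)."""
    if denominator not in ("sum", "max"):
        raise QuantError("denominator must be 'sum' or 'max'")
    by_gene_annotated: Dict[str, List[str]] = {}
    for c in calls:
        if c.status == "annotated":
            by_gene_annotated.setdefault(c.structure.gene_name, []).append(c.name)
    rows = {}
    for c in calls:
        if c.status != "novel":
            continue
        gene = c.structure.gene_name
        ann_names = [n for n in by_gene_annotated.get(gene, []) if n in cm_normalized.index]
        if not ann_names:
            raise QuantError(f"{gene}: no annotated transcripts in the matrix")
        ann = cm_normalized.loc[ann_names]
        denom = ann.sum(axis=0) if denominator == "sum" else ann.max(axis=0)
        num = cm_normalized.loc[c.name]
        rows[c.name] = np.log2((num + pseudocount) / (denom + pseudocount))
    return pd.DataFrame(rows).T


def export_heatmap(
    expression: pd.DataFrame, out_prefix, cluster: bool = True
) -> Dict[str, Optional[Path]]:
    """Write the log2FC matrix as TSV and render a heatmap image
    (red = relatively abundant, blue = rare/undetected)."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = out_prefix.with_suffix(".tsv")
    expression.to_csv(tsv, sep="\t")
    if expression.empty:
        warnings.warn("empty expression table: no heatmap rendered")
        return {"tsv": tsv, "image": None}
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    png = out_prefix.with_suffix(".png")
    if cluster and expression.shape[0] > 1:
        try:
            grid = sns.clustermap(expression, cmap="RdBu_r", center=0.0,
                                  col_cluster=expression.shape[1] > 1)
            grid.savefig(png, dpi=150)
            plt.close(grid.figure)
            return {"tsv": tsv, "image": png}
        except Exception:  # degenerate matrices: fall back to a plain heatmap
            plt.close("all")
    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * expression.shape[1], 1 + 0.35 * expression.shape[0])
    )
    sns.heatmap(expression, cmap="RdBu_r", center=0.0, ax=ax)
    fig.tight_layout()
    fig.savefig(png, dpi=150)
    plt.close(fig)
    return {"tsv": tsv, "image": png}


def quantify(
    evidence: Sequence[ReadEvidence],
    result: CallResult,
    samples: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    denominator: str = "sum",
) -> Dict[str, pd.DataFrame]:
    """Count -> size factors -> normalized counts -> log2FC, in one shot."""
    cm = build_count_matrix(evidence, result.calls, samples)
    factors = mrn_size_factors(cm)
    norm = normalize(cm, factors)
    log2fc = log2fc_table(norm, result.calls, pseudocount, denominator)
    return {
        "counts": cm,
        "size_factors": factors.to_frame(),
        "normalized": norm,
        "log2fc": log2fc,
    }
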