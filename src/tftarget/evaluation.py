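"""Evaluation of ranked predictions against a binary validation matrix.

The validation matrix marks which gene-TF links have independent support
(e.g. ChIP binding near the gene, or ground-truth structure for synthetic
benchmarks).  Rankings are assessed by ROC curves, by the fraction of
top-ranked predictions that are supported (enrichment) with an upper-tail
hypergeometric p-value, and pairs of methods are compared by bootstrap
resampling of the gene set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "roc",
    "hypergeom_pvalue",
    "mark_correct",
    "enrichment_at_cutoffs",
    "bootstrap_compare",
    "single_link_truth",
]


def roc(scores, truth):
    """ROC curve (ties grouped) and trapezoidal AUC.

    Returns (fpr, tpr, auc); requires at least one positive and one negative.
    """
    truth = np.asarray(truth, int)
    scores = np.asarray(scores, float)
    if truth.min() == truth.max():
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, _ = _sk_roc_curve(truth, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def hypergeom_pvalue(k, n, K, N) -> float:
    """Upper-tail P(X >= k) for k supported among n drawn from N with K supported."""
    return float(hypergeom.sf(k - 1, N, K, n))


def single_link_truth(validation: pd.DataFrame, genes, tf_names) -> pd.DataFrame:
    """Validation matrix restricted/reindexed to the given genes and TFs."""
    V = validation.reindex(index=genes, columns=list(tf_names))
    if V.isna().any().any():
        raise ValueError("validation matrix missing entries for requested genes/TFs")
    return V.astype(int)


def mark_correct(ranked: pd.DataFrame, validation: pd.DataFrame, mode="single") -> pd.DataFrame:
    """Attach a boolean ``correct`` column to a ranked prediction list.

    Modes:

    * ``single``: row's link column names one TF; correct iff it is supported.
    * ``pair``: link is "TF1+TF2"; correct iff both are supported.
    * ``map-exact``: row has ``map_structure``; correct iff the predicted
      binary profile matches the validation row exactly (negatives too).
    * ``map-positive``: only predicted regulators must be supported; genes
      predicted unregulated are dropped (they carry no positive claim).
    """
    out = ranked.copy()
    V = validation
    tf_names = list(V.columns)
    if mode == "single":
        out["correct"] = [
            bool(V.at[g, l]) for g, l in zip(out["gene"], out["link"])
        ]
    elif mode == "pair":
        out["correct"] = [
            all(bool(V.at[g, tf]) for tf in l.split("+"))
            for g, l in zip(out["gene"], out["link"])
        ]
    elif mode in ("map-exact", "map-positive"):
        correct, keep = [], []
        for g, st in zip(out["gene"], out["map_structure"]):
            pred = np.array([int(c) for c in st])
            true = V.loc[g].to_numpy()
            if mode == "map-exact":
                keep.append(True)
                correct.append(bool(np.array_equal(pred, true)))
            else:
                if pred.sum() == 0:
                    keep.append(False)
                    correct.append(False)
                else:
                    keep.append(True)
                    correct.append(bool(np.all(true[pred == 1] == 1)))
        out["correct"] = correct
        out = out[np.asarray(keep)].reset_index(drop=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def enrichment_at_cutoffs(ranked: pd.DataFrame, cutoffs) -> pd.DataFrame:
    """Fraction of supported predictions in the top k, with hypergeometric p.

    ``ranked`` must carry a boolean ``correct`` column (see
    :func:`mark_correct`) and be sorted by decreasing confidence.  The
    hypergeometric population is the full ranked list.
    """
    if "correct" not in ranked.columns:
        raise ValueError("ranked list must carry a 'correct' column")
    if len(ranked) == 0:
        raise ValueError("empty ranked list")
    correct = ranked["correct"].to_numpy(bool)
    N = correct.size
    K = int(correct.sum())
    rows = []
    for cutoff in cutoffs:
        if cutoff > N:
            raise ValueError(f"cutoff {cutoff} exceeds list length {N}")
        k = int(correct[:cutoff].sum())
        rows.append(
            {
                "cutoff": int(cutoff),
                "n_correct": k,
                "enrichment": k / cutoff,
                "pvalue": hypergeom_pvalue(k, int(cutoff), K, N),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_compare(
    rankedA: pd.DataFrame,
    rankedB: pd.DataFrame,
    cutoffs,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of bootstrap folds where method A beats B on top-k enrichment.

    Each fold resamples the gene set with replacement; both rankings are
    restricted to the resampled genes (with multiplicity, preserving rank
    order) and their top-k enrichments compared.  Ties count half a win to
    each method.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    genes = sorted(set(rankedA["gene"]) | set(rankedB["gene"]))
    gene_pos = {g: i for i, g in enumerate(genes)}
    G = len(genes)

    def layout(ranked):
        idx = ranked["gene"].map(gene_pos).to_numpy()
        return idx, ranked["correct"].to_numpy(bool)

    idxA, corA = layout(rankedA)
    idxB, corB = layout(rankedB)
    rng = np.random.default_rng(seed)
    cutoffs = [int(c) for c in cutoffs]
    kmax = max(cutoffs)
    wins = {c: 0.0 for c in cutoffs}
    for _ in range(n_boot):
        counts = rng.multinomial(G, np.full(G, 1.0 / G))

        def top_frac(idx, cor):
            mult = counts[idx]
            expanded = np.repeat(cor, mult)[:kmax]
            out = {}
            for c in cutoffs:
                top = expanded[:c]
                out[c] = top.mean() if top.size else 0.0
            return out

        ea = top_frac(idxA, corA)
        eb = top_frac(idxB, corB)
        for c in cutoffs:
            if ea[c] > eb[c]:
                wins[c] += 1.0
            elif ea[c] == eb[c]:
                wins[c] += 0.5
    return pd.DataFrame(
        {"cutoff": cutoffs, "win_fraction": [wins[c] / n_boot for c in cutoffs]}
    )
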