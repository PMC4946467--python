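"""Per-subject fold-change consistency filtering.

Beyond the FDR cut, a gene is only called differentially expressed when
individual subjects agree: each subject's own log2 fold change must exceed
a threshold (default 0.5) in the gene's overall direction, and the fraction
of such subjects — the consistency index — must reach
``(n_subjects - tolerance) / n_subjects``, where the tolerance is the
number of subjects allowed to disagree (0 in the perfusion analysis,
1 in the cold-storage analysis).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def subject_log2fc(cpm: pd.DataFrame, meta: pd.DataFrame,
                   baseline_samples, treated_samples,
                   paired: bool = False, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene, per-subject log2 fold changes on the CPM scale.

    Paired mode matches baseline and treated samples by donor and returns
    ``log2((cpm_treated + pc) / (cpm_baseline + pc))`` per donor; donors
    missing either side are dropped with a warning.  Unpaired mode returns,
    for each treated subject, ``log2(cpm_subject + pc)`` minus the mean of
    ``log2(cpm + pc)`` over all baseline samples.  Columns are donor ids.
    """
    baseline_samples = list(baseline_samples)
    treated_samples = list(treated_samples)
    if not baseline_samples:
        raise ValueError("baseline sample set is empty")
    logc = np.log2(cpm + pseudocount)
    if paired:
        base_by_donor = {meta.loc[s, "donor_id"]: s for s in baseline_samples}
        cols = {}
        for s in treated_samples:
            donor = meta.loc[s, "donor_id"]
            if donor not in base_by_donor:
                warnings.warn(f"donor {donor} lacks a baseline sample; excluded",
                              stacklevel=2)
                continue
            cols[donor] = logc[s] - logc[base_by_donor[donor]]
        if not cols:
            raise ValueError("no complete donor pairs")
        return pd.DataFrame(cols)
    base_mean = logc[baseline_samples].mean(axis=1)
    cols = {meta.loc[s, "donor_id"]: logc[s] - base_mean for s in treated_samples}
    return pd.DataFrame(cols)


def consistency_index(log2fc: pd.DataFrame, fc_threshold: float = 0.5) -> pd.DataFrame:
    """Consistency index per gene from a gene x subject log2FC table.

    The overall direction is the sign of the mean per-subject log2FC
    (exact ties break to 'up' and are flagged).  A subject is consistent
    when its log2FC, signed in the overall direction, strictly exceeds
    ``fc_threshold``.  Returns columns ``direction, c, n_consistent, n, tie``.
    """
    if log2fc.shape[1] < 1:
        raise ValueError("need at least one subject")
    vals = log2fc.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    tie = mean == 0.0
    up = mean >= 0.0
    signed = np.where(up[:, None], vals, -vals)
    n_consistent = (signed > fc_threshold).sum(axis=1)
    n = vals.shape[1]
    return pd.DataFrame({
        "direction": np.where(up, "up", "down"),
        "c": n_consistent / n,
        "n_consistent": n_consistent,
        "n": n,
        "tie": tie,
    }, index=log2fc.index)


def index_threshold(n_subjects: int, tolerance: int) -> float:
    """Minimum consistency index given an inconsistent-subject tolerance."""
    if not 0 <= tolerance <= n_subjects:
        raise ValueError("tolerance must lie in [0, n_subjects]")
    return (n_subjects - tolerance) / n_subjects


def call_de(de: pd.DataFrame, cons: pd.DataFrame,
            fdr_threshold: float, tolerance: int) -> pd.DataFrame:
    """Genes passing both the FDR cut and the consistency check.

    ``de`` needs a ``q`` column and ``cons`` the columns produced by
    :func:`consistency_index`; both must be indexed by the same genes.
    """
    if set(de.index) != set(cons.index):
        raise ValueError("DE and consistency tables index different genes")
    cons = cons.loc[de.index]
    thresholds = (cons["n"] - tolerance) / cons["n"]
    called = (de["q"] <= fdr_threshold) & (cons["c"] >= thresholds)
    out = pd.DataFrame({
        "direction": cons["direction"],
        "q": de["q"],
        "c": cons["c"],
    }, index=de.index)
    return out[called.to_numpy()]


def dcd_specific_sets(de_dcd: pd.Series, de_dbd: pd.Series):
    """Partition the DCD-only DE genes by direction.

    Both inputs map gene -> direction ('up'/'down').  Returns a
    :class:`~liverseq.datatypes.GeneSetCall`.
    """
    from .datatypes import GeneSetCall

    specific = [g for g in de_dcd.index if g not in set(de_dbd.index)]
    up = sorted(g for g in specific if de_dcd[g] == "up")
    down = sorted(g for g in specific if de_dcd[g] == "down")
    return GeneSetCall(de_dcd=de_dcd, de_dbd=de_dbd,
                       dcd_specific_up=up, dcd_specific_down=down)
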