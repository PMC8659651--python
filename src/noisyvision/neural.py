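"""Voxel-pattern preprocessing, decoding, and representational similarity.

Implements the response-pattern side of the pipeline from percent signal
change onward: amplitude extraction (mean of TRs 3-5 post-onset, 1-based
inclusive), per-run z-normalization, leave-one-run-out multiclass SVM
decoding, a subject inclusion criterion, representational dissimilarity
matrices (pairwise Pearson pattern correlations), RSA comparison between
systems, and group-level statistics on Fisher-z-transformed correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

__all__ = [
    "ResponseAmplitudeSet",
    "normalize_by_run",
    "amplitudes_from_timeseries",
    "decode_category",
    "qc_subject",
    "build_rdm",
    "rsa_compare",
    "group_layer_profile",
]


@dataclass
class ResponseAmplitudeSet:
    """Trial-by-voxel amplitudes with run / condition / stimulus labels."""

    responses: np.ndarray     # (n_trials, n_voxels)
    run: np.ndarray           # (n_trials,) int
    stimulus: np.ndarray      # (n_trials,) stimulus id
    condition: np.ndarray     # (n_trials,) str
    category: np.ndarray      # (n_trials,) category label for decoding
    normalized: bool = False
    zero_variance_runs: tuple = ()

    def select(self, condition=None, runs=None, exclude_runs=None):
        sel = np.ones(len(self.run), dtype=bool)
        if condition is not None:
            sel &= self.condition == condition
        if runs is not None:
            sel &= np.isin(self.run, runs)
        if exclude_runs is not None:
            sel &= ~np.isin(self.run, exclude_runs)
        return replace(
            self,
            responses=self.responses[sel], run=self.run[sel],
            stimulus=self.stimulus[sel], condition=self.condition[sel],
            category=self.category[sel],
        )


def normalize_by_run(data: ResponseAmplitudeSet) -> ResponseAmplitudeSet:
    """Z-normalize each run's amplitudes to overall mean 0 and SD 1."""
    out = data.responses.astype(float).copy()
    flagged = []
    for r in np.unique(data.run):
        sel = data.run == r
        block = out[sel]
        sd = block.std()
        if sd == 0:
            flagged.append(int(r))
            out[sel] = 0.0
        else:
            out[sel] = (block - block.mean()) / sd
    return replace(data, responses=out, normalized=True, zero_variance_runs=tuple(flagged))


def amplitudes_from_timeseries(runs) -> ResponseAmplitudeSet:
    """Stimulus response amplitudes from raw voxel time series.

    ``runs`` is a list of dicts, one per acquisition run, with keys
    ``series`` -- a (n_TR, n_voxels) array -- and ``onsets`` -- a list of
    ``(tr_index, stimulus_id, condition, category)`` tuples where
    ``tr_index`` is the 0-based TR at stimulus onset.  Each voxel's series
    is converted to percent signal change relative to its run mean, the
    amplitude is the mean over TRs 3-5 post-onset (1-based inclusive, i.e.
    array offsets +2..+4), and amplitudes are then z-normalized per run.
    Trials whose window extends past the run end are dropped.
    """
    amps, run_l, stim_l, cond_l, cat_l = [], [], [], [], []
    for r, rd in enumerate(runs):
        series = np.asarray(rd["series"], dtype=float)
        mean = series.mean(axis=0)
        if np.any(mean == 0):
            raise ValueError(f"run {r} has zero-mean voxels; cannot form percent signal change")
        psc = 100.0 * (series - mean) / mean
        for onset in rd["onsets"]:
            t0, stim, cond, cat = onset
            if t0 + 5 > len(series):
                continue  # window extends past run end: trial dropped
            amps.append(psc[t0 + 2 : t0 + 5].mean(axis=0))
            run_l.append(r)
            stim_l.append(stim)
            cond_l.append(cond)
            cat_l.append(cat)
    data = ResponseAmplitudeSet(
        responses=np.array(amps), run=np.array(run_l),
        stimulus=np.array(stim_l), condition=np.array(cond_l),
        category=np.array(cat_l),
    )
    return normalize_by_run(data)


def decode_category(
    data: ResponseAmplitudeSet, train_condition: str, test_condition: str
) -> float:
    """Leave-one-run-out multiclass SVM decoding accuracy.

    Per fold, a linear SVM (one-vs-one, C=1 -- default settings) is trained
    on ``train_condition`` trials of the held-in runs and tested on
    ``test_condition`` trials of the held-out run; training strictly never
    sees the held-out run in any condition.  Folds whose training set misses
    a category are skipped.
    """
    runs = np.unique(data.run)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out decoding")
    n_cat = len(np.unique(data.category))
    accs = []
    for held_out in runs:
        train = data.select(condition=train_condition, exclude_runs=[held_out])
        test = data.select(condition=test_condition, runs=[held_out])
        if len(np.unique(train.category)) < n_cat or len(test.category) == 0:
            continue
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(train.responses, train.category)
        accs.append(float(np.mean(clf.predict(test.responses) == test.category)))
    if not accs:
        raise ValueError("no usable folds: every training fold missed a category")
    return float(np.mean(accs))


def qc_subject(v1_accuracy_by_condition, minimum: float = 0.20) -> bool:
    """Subject inclusion: mean V1 accuracy across conditions must reach 20%."""
    accs = np.asarray(list(v1_accuracy_by_condition), dtype=float)
    if accs.size != 3:
        raise ValueError("expected accuracies for 3 viewing conditions")
    return bool(accs.mean() >= minimum)


def build_rdm(patterns: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation matrix between row patterns.

    Zero-variance patterns yield NaN entries (flagged undefined) rather than
    raising.
    """
    P = np.asarray(patterns, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 stimuli")
    sd = P.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rdm = np.corrcoef(P)
    rdm[sd == 0, :] = np.nan
    rdm[:, sd == 0] = np.nan
    np.fill_diagonal(rdm, 1.0)
    return rdm


def rsa_compare(rdm_a: np.ndarray, rdm_b: np.ndarray) -> tuple[float, float]:
    """Pearson r between two RDMs over the off-diagonal upper triangle.

    Returns ``(r, fisher_z)`` with ``fisher_z = atanh(r)``.
    """
    a = np.asarray(rdm_a, dtype=float)
    b = np.asarray(rdm_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("RDM size mismatch")
    iu = np.triu_indices(a.shape[0], k=1)
    va, vb = a[iu], b[iu]
    ok = np.isfinite(va) & np.isfinite(vb)
    r = float(np.corrcoef(va[ok], vb[ok])[0, 1])
    return r, float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))


def group_layer_profile(
    per_subject_r: np.ndarray,
    alpha: float = 0.01,
    paired_against: np.ndarray | None = None,
) -> pd.DataFrame:
    """Group statistics on subject x layer RSA correlations.

    Correlations are Fisher-z-transformed; per layer, a two-sided one-sample
    t test against zero (or a paired t test against a second model's
    correlations) is run, flagging layers at ``p < alpha`` uncorrected.
    Layers with zero variance across subjects are flagged and given p = 1.
    """
    R = np.atleast_2d(np.asarray(per_subject_r, dtype=float))
    if R.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    Z = np.arctanh(np.clip(R, -1 + 1e-15, 1 - 1e-15))
    rows = []
    for j in range(Z.shape[1]):
        z = Z[:, j]
        if paired_against is not None:
            z2 = np.arctanh(np.clip(np.asarray(paired_against, dtype=float)[:, j], -1 + 1e-15, 1 - 1e-15))
            diff = z - z2
            zero_var = np.allclose(diff, diff[0])
            t, p = (0.0, 1.0) if zero_var else stats.ttest_rel(z, z2)
        else:
            zero_var = np.allclose(z, z[0])
            t, p = (0.0, 1.0) if zero_var else stats.ttest_1samp(z, 0.0)
        rows.append(
            {
                "layer": j,
                "mean_r": float(np.tanh(z.mean())),
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
                "zero_variance": zero_var,
            }
        )
    return pd.DataFrame(rows)
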