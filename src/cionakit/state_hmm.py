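"""Eight-state Gaussian HMM over postural features and its readouts.

Each frame is described by the five static eigenciona scores, their
within-animal first differences (dynamic components), and the postural
speed and acceleration (norms of the first and second differences of the
score trajectory) — all z-scored within animal.  One HMM is trained on
the pooled conditions and decoded per animal; decoded bouts shorter than
the 5-frame duration threshold are merged into the neighboring state with
the higher posterior mass.  States are relabeled deterministically
(ascending mean of a caller-supplied ordering signal, by default the
first feature) so S0..S7 are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

__all__ = [
    "HMMFeatures", "HMMModel", "StateMetrics",
    "build_features", "fit_hmm", "decode", "state_metrics",
    "hmm_transition_analysis",
]


@dataclass
class HMMFeatures:
    """Stacked per-frame features with animal bookkeeping.

    ``values`` is (T_total, n_features); ``mask`` marks frames with
    defined derivatives (the first two frames of each animal are masked).
    """

    values: np.ndarray
    animal_ids: np.ndarray
    mask: np.ndarray
    feature_names: list

    def per_animal(self):
        for animal in pd.unique(self.animal_ids):
            sel = (self.animal_ids == animal) & self.mask
            yield animal, self.values[sel], np.nonzero(sel)[0]


@dataclass
class HMMModel:
    model: GaussianHMM
    n_states: int
    state_order: np.ndarray        # raw hmmlearn label -> ordered S index
    min_bout: int = 5
    feature_names: list = field(default_factory=list)

    @property
    def transition_matrix(self) -> np.ndarray:
        perm = np.argsort(self.state_order)
        return self.model.transmat_[np.ix_(perm, perm)]

    @property
    def means(self) -> np.ndarray:
        return self.model.means_[np.argsort(self.state_order)]


@dataclass
class StateMetrics:
    occupancy: pd.DataFrame        # condition x state fractions
    bout_duration: pd.DataFrame    # condition x state median dwell (s)
    fold_change: pd.DataFrame | None = None


def _zscore_within(x: np.ndarray) -> np.ndarray:
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def build_features(ec_scores_by_animal: dict) -> HMMFeatures:
    """Assemble and z-score the HMM feature set per animal.

    ``ec_scores_by_animal`` maps animal id to its (T, 5) EC score
    trajectory.  Features: EC scores, their first differences, speed
    (norm of the first difference) and acceleration (norm of the second
    difference); derivatives never cross animal boundaries.
    """
    blocks, ids, masks = [], [], []
    names = None
    for animal, scores in ec_scores_by_animal.items():
        S = np.asarray(scores, dtype=float)
        if len(S) < 3:
            import warnings
            warnings.warn(f"animal {animal!r} has < 3 frames; excluded")
            continue
        k = S.shape[1]
        d1 = np.vstack([np.full((1, k), np.nan), np.diff(S, axis=0)])
        d2 = np.vstack([np.full((2, k), np.nan), np.diff(S, n=2, axis=0)])
        speed = np.linalg.norm(d1, axis=1, keepdims=True)
        accel = np.linalg.norm(d2, axis=1, keepdims=True)
        feats = np.hstack([S, d1, speed, accel])
        feats = _zscore_within(feats)
        blocks.append(feats)
        ids.append(np.full(len(S), animal, dtype=object))
        masks.append(np.all(np.isfinite(feats), axis=1))
        if names is None:
            names = ([f"EC{i+1}" for i in range(k)]
                     + [f"dEC{i+1}" for i in range(k)] + ["speed", "accel"])
    if not blocks:
        raise ValueError("no usable animals")
    return HMMFeatures(values=np.vstack(blocks), animal_ids=np.concatenate(ids),
                       mask=np.concatenate(masks), feature_names=names)


def _enforce_min_bout(states: np.ndarray, posteriors: np.ndarray,
                      min_bout: int) -> np.ndarray:
    """Merge bouts shorter than ``min_bout`` into the neighbor with the
    higher mean posterior mass over the bout's frames."""
    s = states.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, len(s) + 1):
            if i == len(s) or s[i] != s[start]:
                runs.append((s[start], start, i))
                start = i
        if len(runs) <= 1:
            break
        for j, (state, a, b) in enumerate(runs):
            if b - a >= min_bout:
                continue
            left = runs[j - 1][0] if j > 0 else None
            right = runs[j + 1][0] if j < len(runs) - 1 else None
            if left is None:
                target = right
            elif right is None:
                target = left
            else:
                pl = posteriors[a:b, left].mean()
                pr = posteriors[a:b, right].mean()
                target = left if pl >= pr else right
            s[a:b] = target
            changed = True
            break
    return s


def fit_hmm(features: HMMFeatures, n_states: int = 8, *, seed: int = 0,
            n_restarts: int = 10, covariance_type: str = "diag",
            n_iter: int = 500, tol: float = 1e-4, min_bout: int = 5,
            ordering_values: np.ndarray | None = None,
            ) -> tuple[HMMModel, dict]:
    """EM fit on pooled animals (best of ``n_restarts``), Viterbi decode.

    ``ordering_values`` is a per-frame signal (aligned with the unmasked
    feature rows) whose ascending per-state mean defines the S0..S7
    relabeling — by convention the whole-body-area z-trend, so S0 is the
    most relaxed and S7 the most contracted state.  Returns the model and
    ``{animal: ordered decoded sequence}``.
    """
    X = features.values[features.mask]
    lengths = [int(np.sum((features.animal_ids == a) & features.mask))
               for a in pd.unique(features.animal_ids)]
    lengths = [l for l in lengths if l > 0]
    best, best_ll = None, -np.inf
    failures = []
    for r in range(n_restarts):
        try:
            hm = GaussianHMM(n_components=n_states, covariance_type=covariance_type,
                             n_iter=n_iter, tol=tol, random_state=seed + r)
            hm.fit(X, lengths)
            ll = hm.score(X, lengths)
        except Exception as exc:
            failures.append(str(exc))
            continue
        if ll > best_ll:
            best, best_ll = hm, ll
    if best is None:
        raise RuntimeError(f"EM failed across all restarts: {failures}")

    raw = best.predict(X, lengths)
    # ordering key: ascending mean of the ordering signal per raw state
    key_signal = (np.asarray(ordering_values, dtype=float)
                  if ordering_values is not None else X[:, 0])
    means = np.array([key_signal[raw == k].mean() if np.any(raw == k) else np.inf
                      for k in range(n_states)])
    state_order = np.empty(n_states, dtype=int)
    state_order[np.argsort(means)] = np.arange(n_states)  # raw -> ordered

    model = HMMModel(model=best, n_states=n_states, state_order=state_order,
                     min_bout=min_bout, feature_names=features.feature_names)
    decoded = decode(model, features)
    return model, decoded


def decode(model: HMMModel, features: HMMFeatures) -> dict:
    """Viterbi per animal, minimum-bout enforcement, ordered labels."""
    out = {}
    for animal, X, _ in features.per_animal():
        states = model.model.predict(X)
        post = model.model.predict_proba(X)
        states = _enforce_min_bout(states, post, model.min_bout)
        out[animal] = model.state_order[states]
    return out


def _bouts(seq: np.ndarray):
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            yield int(seq[start]), start, i
            start = i


def state_metrics(decoded: dict, condition_of: dict, fps: float,
                  n_states: int = 8, baseline: str | None = None) -> StateMetrics:
    """Occupancy and median bout duration per state per condition.

    With a ``baseline`` condition, fold changes (condition / baseline) are
    attached; states absent from the baseline report NaN.
    """
    conditions = sorted({condition_of[a] for a in decoded}, key=str)
    occ = pd.DataFrame(0.0, index=conditions, columns=range(n_states))
    dur = pd.DataFrame(np.nan, index=conditions, columns=range(n_states))
    for cond in conditions:
        seqs = [decoded[a] for a in decoded if condition_of[a] == cond]
        total = sum(len(s) for s in seqs)
        counts = np.zeros(n_states)
        durations: dict = {k: [] for k in range(n_states)}
        for s in seqs:
            counts += np.bincount(s, minlength=n_states)
            for state, a, b in _bouts(s):
                durations[state].append((b - a) / fps)
        occ.loc[cond] = counts / total if total else 0.0
        for k in range(n_states):
            if durations[k]:
                dur.loc[cond, k] = float(np.median(durations[k]))
    fold = None
    if baseline is not None:
        if baseline not in conditions:
            raise ValueError(f"baseline condition {baseline!r} not present")
        with np.errstate(divide="ignore", invalid="ignore"):
            occ_fc = occ.div(occ.loc[baseline], axis=1)
            dur_fc = dur.div(dur.loc[baseline], axis=1)
        zero_base = (occ.loc[baseline] == 0).to_numpy()
        occ_fc.loc[:, zero_base] = np.nan
        fold = pd.concat({"occupancy": occ_fc, "bout_duration": dur_fc}, axis=0)
    occ.columns = dur.columns = [f"S{k}" for k in range(n_states)]
    if fold is not None:
        fold.columns = [f"S{k}" for k in range(n_states)]
    return StateMetrics(occupancy=occ, bout_duration=dur, fold_change=fold)


def hmm_transition_analysis(decoded: dict, condition_of: dict,
                            n_states: int = 8) -> dict:
    """Frame-to-frame transition probabilities per condition.

    Self-transitions are meaningful at the HMM level (state persistence);
    returns ``{condition: {"frame": P, "bout": P, "counts": C}}`` plus
    pairwise condition difference maps under the key ``"differences"``.
    """
    conditions = sorted({condition_of[a] for a in decoded}, key=str)
    out: dict = {}
    for cond in conditions:
        seqs = [decoded[a] for a in decoded if condition_of[a] == cond]
        frame_counts = np.zeros((n_states, n_states))
        bout_counts = np.zeros((n_states, n_states))
        n_bouts = 0
        for s in seqs:
            for i, j in zip(s[:-1], s[1:]):
                frame_counts[i, j] += 1
            prev = None
            for state, *_ in _bouts(s):
                if prev is not None:
                    bout_counts[prev, state] += 1
                prev = state
                n_bouts += 1
        if n_bouts < 2:
            import warnings
            warnings.warn(f"condition {cond!r}: fewer than 2 bouts; skipped")
            continue

        def _norm(c):
            rows = c.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(rows > 0, c / rows, 0.0)

        out[cond] = {"counts": frame_counts, "frame": _norm(frame_counts),
                     "bout": _norm(bout_counts)}
    diffs = {}
    conds = list(out)
    for i, c1 in enumerate(conds):
        for c2 in conds[i + 1:]:
            diffs[(c1, c2)] = out[c2]["frame"] - out[c1]["frame"]
    out["differences"] = diffs
    return out
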