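"""Spy-based positive-unlabeled learning.

Phase A (spy extraction): a seeded fraction of the positives is planted in
the unlabeled pool with a negative label. After training, the spy scores
calibrate how hidden positives behave: the threshold is the largest score at
which (almost) all spies are still classified positive, and unlabeled
examples scoring strictly below it become reliable negatives (RN). The loop
re-trains and re-thresholds with the same spy set until RN stops changing.

Phase B (expansion): train positives vs RN, classify the undecided set Q by
the 0.5 posterior rule, move the negatives into RN, repeat until no example
in Q is classified negative.

The modified variant replaces both phases with a single loop that draws a
fresh spy set each iteration, trains positives-minus-spies against
RN + Q + spies, and applies that iteration's spy threshold to Q.

Either way the final classifier is trained on the full original positive
set against the converged RN set.
"""

from __future__ import annotations

import csv
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifier import NEGATIVE, POSITIVE, ProbClassifier, make_classifier
from .datasets import PUDataset, SequenceRecord
from .seqfeatures import FeatureConfig, featurize, featurize_records

logger = logging.getLogger(__name__)

VARIANTS = ("original", "modified")


@dataclass(frozen=True)
class SpyConfig:
    """Parameters of the spy loop.

    ``n_spies`` overrides the rounded ``s * |P|`` spy count when set (the
    published configuration used 30 spies out of 232 positives, which no
    rounding of 15% reproduces exactly).
    """

    s: float = 0.15
    seed: int = 0
    variant: str = "original"
    max_iter: int = 100
    n_spies: int | None = None
    spy_noise: float = 0.15
    classifier: str = "tree"
    classifier_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.s < 1):
            raise ValueError(f"spy fraction s must be in (0, 1), got {self.s}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0 <= self.spy_noise < 1):
            raise ValueError(f"spy_noise must be in [0, 1), got {self.spy_noise}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")


@dataclass(frozen=True)
class IterationRecord:
    phase: str  # "spy" or "expand"
    iteration: int
    n_rn: int
    n_q: int
    threshold: float
    spy_ids: tuple[str, ...]


@dataclass
class PUState:
    """Evolving partition of the unlabeled pool into RN and Q."""

    rn: set[str]
    q: set[str]
    iteration: int
    history: list[IterationRecord] = field(default_factory=list)
    converged: bool = False

    def check_partition(self, u_ids: set[str]) -> None:
        if self.rn & self.q:
            raise AssertionError("RN and Q overlap")
        if self.rn | self.q != u_ids:
            raise AssertionError("RN and Q do not partition U")


@dataclass
class PUModel:
    """Converged final classifier plus the configuration that produced it."""

    final_classifier: ProbClassifier
    state: PUState
    spy_config: SpyConfig
    feature_config: FeatureConfig
    p_ids: list[str]
    converged: bool

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "PUModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, PUModel):
            raise ValueError(f"{path} does not contain a PUModel")
        return model


@dataclass(frozen=True)
class Prediction:
    id: str
    label: str  # "positive" / "negative"
    prob_positive: float
    zero_effective_length: bool = False


def select_spies(
    p_ids: Sequence[str], s: float, seed: int, n_spies: int | None = None
) -> tuple[list[str], list[str]]:
    """Draw the spy set S uniformly without replacement; return (S, P \\ S).

    The spy count is round-half-away-from-zero of ``s * |P|`` unless
    ``n_spies`` overrides it. Input order is preserved in both outputs.
    """
    if len(p_ids) < 2:
        raise ValueError("need at least 2 positives to draw spies")
    n = n_spies if n_spies is not None else int(np.floor(s * len(p_ids) + 0.5))
    if n < 1 or n >= len(p_ids):
        raise ValueError(
            f"spy fraction degenerate: {n} spies from {len(p_ids)} positives"
        )
    rng = np.random.default_rng(seed)
    spy_idx = set(rng.choice(len(p_ids), size=n, replace=False).tolist())
    S = [p for i, p in enumerate(p_ids) if i in spy_idx]
    P_rest = [p for i, p in enumerate(p_ids) if i not in spy_idx]
    return S, P_rest


def spy_threshold(spy_probs: Sequence[float], noise: float = 0.0) -> float:
    """Largest threshold keeping at least a (1 - noise) fraction of spies positive.

    With ``noise = 0`` this is the minimum spy probability — the largest t at
    which *every* spy is classified positive. A non-zero noise level tolerates
    that many spies scoring below t: with n spies, the floor(noise * n) lowest
    spy probabilities are ignored and t is the next one up. Outlier positives
    drawn as spies otherwise pin t to the bottom of the score range and no
    reliable negative can ever be extracted.
    """
    probs = np.asarray(spy_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("spy_probs must be non-empty")
    if not (0 <= noise < 1):
        raise ValueError(f"noise must be in [0, 1), got {noise}")
    k = int(np.floor(noise * probs.size))
    return float(np.sort(probs)[k])


class _Pool:
    """Feature rows of the unlabeled pool, addressable by id."""

    def __init__(self, u_ids: Sequence[str], u_X: np.ndarray):
        self.ids = list(u_ids)
        self.X = np.asarray(u_X, dtype=float)
        self.row = {rec_id: i for i, rec_id in enumerate(self.ids)}

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        return self.X[[self.row[i] for i in ids]]


def _fit(cfg: SpyConfig, X: np.ndarray, y: np.ndarray, seed: int) -> ProbClassifier:
    clf = make_classifier(cfg.classifier, seed=seed, **cfg.classifier_params)
    clf.fit(X, y)
    return clf


def extract_rn_spy(
    p_ids: Sequence[str],
    p_X: np.ndarray,
    u_ids: Sequence[str],
    u_X: np.ndarray,
    cfg: SpyConfig,
) -> PUState:
    """Phase A of the original variant: one spy draw, iterate to convergence.

    Training assignments are fixed for the whole phase — P \\ S is the
    positive class, U + S the negative class (reliable negatives keep their
    negative label when moved out of the undecided set). Only the undecided
    non-spy examples are candidates for RN.
    """
    if len(u_ids) < 1:
        raise ValueError("U must be non-empty")
    p_ids = list(p_ids)
    pool = _Pool(u_ids, u_X)
    S, P_rest = select_spies(p_ids, cfg.s, cfg.seed, cfg.n_spies)
    p_row = {rec_id: i for i, rec_id in enumerate(p_ids)}
    spy_X = np.asarray(p_X, dtype=float)[[p_row[i] for i in S]]
    rest_X = np.asarray(p_X, dtype=float)[[p_row[i] for i in P_rest]]

    X_train = np.vstack([rest_X, pool.X, spy_X])
    y_train = np.concatenate(
        [np.full(len(P_rest), POSITIVE), np.full(len(pool.ids) + len(S), NEGATIVE)]
    )

    state = PUState(rn=set(), q=set(pool.ids), iteration=0)
    for _ in range(cfg.max_iter):
        state.iteration += 1
        clf = _fit(cfg, X_train, y_train, seed=cfg.seed)
        t = spy_threshold(clf.predict_proba_pos(spy_X), cfg.spy_noise)
        q_ids = sorted(state.q)
        q_probs = clf.predict_proba_pos(pool.rows(q_ids)) if q_ids else np.empty(0)
        moved = {rec_id for rec_id, p in zip(q_ids, q_probs) if p < t}
        state.rn |= moved
        state.q -= moved
        state.history.append(
            IterationRecord("spy", state.iteration, len(state.rn), len(state.q), t, tuple(S))
        )
        if state.iteration == 1 and not state.rn:
            raise ValueError(
                "no reliable negatives — classes inseparable or spy fraction too small"
            )
        if not moved:
            state.converged = True
            break
    if not state.converged:
        logger.warning("spy extraction hit max_iter=%d without converging", cfg.max_iter)
    return state


def expand_rn(
    p_ids: Sequence[str],
    p_X: np.ndarray,
    state: PUState,
    u_ids: Sequence[str],
    u_X: np.ndarray,
    cfg: SpyConfig,
) -> PUState:
    """Phase B: train full P vs RN, move Q examples classified negative.

    "Classified negative" is the plain 0.5 posterior cut — no spy threshold
    is in scope here. Stops as soon as an iteration moves nothing.
    """
    if not state.rn:
        raise ValueError("expand_rn requires a non-empty RN set")
    pool = _Pool(u_ids, u_X)
    p_X = np.asarray(p_X, dtype=float)
    state.converged = False
    for _ in range(cfg.max_iter):
        q_ids = sorted(state.q)
        if not q_ids:
            state.converged = True
            break
        state.iteration += 1
        rn_ids = sorted(state.rn)
        X_train = np.vstack([p_X, pool.rows(rn_ids)])
        y_train = np.concatenate([np.full(len(p_ids), POSITIVE), np.full(len(rn_ids), NEGATIVE)])
        clf = _fit(cfg, X_train, y_train, seed=cfg.seed)
        q_probs = clf.predict_proba_pos(pool.rows(q_ids))
        W = {rec_id for rec_id, p in zip(q_ids, q_probs) if p < 0.5}
        state.rn |= W
        state.q -= W
        state.history.append(
            IterationRecord("expand", state.iteration, len(state.rn), len(state.q), 0.5, ())
        )
        if not W:
            state.converged = True
            break
    if not state.converged:
        logger.warning("RN expansion hit max_iter=%d without converging", cfg.max_iter)
    return state


def _run_modified(
    p_ids: list[str], p_X: np.ndarray, pool: _Pool, cfg: SpyConfig
) -> PUState:
    """Modified spy variant: a fresh seeded spy draw every iteration."""
    p_row = {rec_id: i for i, rec_id in enumerate(p_ids)}
    state = PUState(rn=set(), q=set(pool.ids), iteration=0)
    for _ in range(cfg.max_iter):
        state.iteration += 1
        # iteration 1 reuses the phase-A draw seed so that, for a shared config
        # seed, the first iteration of both variants is the same computation
        S, P_rest = select_spies(p_ids, cfg.s, cfg.seed + state.iteration - 1, cfg.n_spies)
        spy_X = p_X[[p_row[i] for i in S]]
        rest_X = p_X[[p_row[i] for i in P_rest]]
        X_train = np.vstack([rest_X, pool.X, spy_X])
        y_train = np.concatenate(
            [np.full(len(P_rest), POSITIVE), np.full(len(pool.ids) + len(S), NEGATIVE)]
        )
        clf = _fit(cfg, X_train, y_train, seed=cfg.seed)
        t = spy_threshold(clf.predict_proba_pos(spy_X), cfg.spy_noise)
        q_ids = sorted(state.q)
        q_probs = clf.predict_proba_pos(pool.rows(q_ids)) if q_ids else np.empty(0)
        moved = {rec_id for rec_id, p in zip(q_ids, q_probs) if p < t}
        state.rn |= moved
        state.q -= moved
        state.history.append(
            IterationRecord("spy", state.iteration, len(state.rn), len(state.q), t, tuple(S))
        )
        if state.iteration == 1 and not state.rn:
            raise ValueError(
                "no reliable negatives — classes inseparable or spy fraction too small"
            )
        if not moved:
            state.converged = True
            break
    if not state.converged:
        logger.warning("modified spy loop hit max_iter=%d without converging", cfg.max_iter)
    return state


def run_pu(
    dataset: PUDataset,
    feature_config: FeatureConfig | None = None,
    cfg: SpyConfig | None = None,
) -> PUModel:
    """Run the full PU protocol and train the final classifier.

    The final classifier always uses the complete original positive set
    (spies included) against the converged RN set.
    """
    fcfg = feature_config if feature_config is not None else FeatureConfig()
    cfg = cfg if cfg is not None else SpyConfig()
    p_ids, p_X = featurize_records(dataset.P, fcfg)
    u_ids, u_X = featurize_records(dataset.U, fcfg)
    pool = _Pool(u_ids, u_X)

    if cfg.variant == "original":
        state = extract_rn_spy(p_ids, p_X, u_ids, u_X, cfg)
        state = expand_rn(p_ids, p_X, state, u_ids, u_X, cfg)
    else:
        state = _run_modified(p_ids, p_X, pool, cfg)
    state.check_partition(set(u_ids))

    rn_ids = sorted(state.rn)
    X_final = np.vstack([p_X, pool.rows(rn_ids)])
    y_final = np.concatenate([np.full(len(p_ids), POSITIVE), np.full(len(rn_ids), NEGATIVE)])
    final_clf = _fit(cfg, X_final, y_final, seed=cfg.seed)
    return PUModel(
        final_classifier=final_clf,
        state=state,
        spy_config=cfg,
        feature_config=fcfg,
        p_ids=p_ids,
        converged=state.converged,
    )


def predict(model: PUModel, records: Sequence[SequenceRecord]) -> list[Prediction]:
    """Score sequences with the final classifier; positive iff Pr >= 0.5."""
    out: list[Prediction] = []
    if not records:
        return out
    vectors = [featurize(r.seq, model.feature_config) for r in records]
    X = np.vstack([v.to_array() for v in vectors])
    probs = model.final_classifier.predict_proba_pos(X)
    for rec, vec, p in zip(records, vectors, probs):
        out.append(
            Prediction(
                id=rec.id,
                label="positive" if p >= 0.5 else "negative",
                prob_positive=float(p),
                zero_effective_length=vec.effective_length == 0,
            )
        )
    return out


def write_history(state: PUState, path: str | Path) -> None:
    """Per-iteration history TSV: the plot-ready convergence-curve artifact."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["phase", "iteration", "n_rn", "n_q", "threshold"])
        for rec in state.history:
            writer.writerow(
                [rec.phase, rec.iteration, rec.n_rn, rec.n_q, format(rec.threshold, ".6g")]
            )
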