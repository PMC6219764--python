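"""Report-to-label inference.

A bag-of-words (1- and 2-gram) Lasso logistic classifier infers a finding
label from free-text radiology reports; negation is not modelled
explicitly, so bigrams like "no pneumonia" have to carry it. Hernia, too
rare to model, gets a keyword rule: the report is positive iff the whole
token "hernia" appears (case-insensitive).
"""

from __future__ import annotations

import json
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

_TOKEN_RE = re.compile(r"[a-z0-9]+")

DEFAULT_L1_GRID = (0.03, 0.1, 0.3, 1.0, 3.0, 10.0)  # inverse penalty C values


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric boundaries."""
    return _TOKEN_RE.findall(text.lower())


def ngrams(text: str) -> list[str]:
    """Unigrams plus space-joined bigrams."""
    tokens = tokenize(text)
    return tokens + [f"{a} {b}" for a, b in zip(tokens, tokens[1:])]


def featurize(text: str) -> Counter:
    """Sparse n-gram count vector as a Counter; empty text -> empty."""
    return Counter(ngrams(text))


def apply_hernia_rule(text: str) -> int:
    """1 iff the whole word "hernia" occurs, case-insensitively.

    Matches tokens, not substrings, so e.g. "herniation" does not fire.
    """
    return int("hernia" in tokenize(text))


@dataclass
class NgramLabelModel:
    """Fitted Lasso logistic model over an n-gram count vocabulary."""

    vocabulary: list[str]
    coefficients: np.ndarray
    intercept: float
    c: float  # inverse L1 regularization strength actually used
    threshold: float = 0.5
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.vocabulary):
            raise ValueError("coefficient vector must match vocabulary length")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def _matrix(self, texts) -> sparse.csr_matrix:
        index = {g: i for i, g in enumerate(self.vocabulary)}
        rows, cols, data = [], [], []
        for i, text in enumerate(texts):
            for gram, count in featurize(text).items():
                j = index.get(gram)
                if j is not None:  # out-of-vocabulary n-grams are ignored
                    rows.append(i)
                    cols.append(j)
                    data.append(count)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(list(texts)), len(self.vocabulary))
        )

    def predict_proba(self, texts) -> np.ndarray:
        texts = list(texts)
        z = self._matrix(texts) @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, texts) -> np.ndarray:
        return (self.predict_proba(texts) >= self.threshold).astype(int)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "vocabulary": self.vocabulary,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "c": self.c,
            "threshold": self.threshold,
            "metrics": self.metrics,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NgramLabelModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            vocabulary=payload["vocabulary"],
            coefficients=np.array(payload["coefficients"]),
            intercept=payload["intercept"],
            c=payload["c"],
            threshold=payload["threshold"],
            metrics=payload.get("metrics", {}),
        )


def _fit_lasso(x, y, c: float, seed: int) -> LogisticRegression:
    lr = LogisticRegression(
        l1_ratio=1.0, C=c, solver="liblinear", random_state=seed, max_iter=1000
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        lr.fit(x, y)
    return lr


def fit_label_model(
    docs,
    labels,
    l1_grid=DEFAULT_L1_GRID,
    folds: int = 5,
    seed: int = 0,
    holdout_fraction: float | int = 0.3,
) -> NgramLabelModel:
    """Fit the n-gram Lasso labeler with cross-validated penalty selection.

    The corpus is split into a working and a held-out part (stratified;
    ``holdout_fraction`` may be a fraction or an absolute document count);
    the L1 strength is chosen by cross-validated log-loss on the working
    part; held-out AUC, sensitivity and specificity at the 50% threshold
    are recorded; the final model is refit on the full corpus with the
    chosen penalty. Deterministic given the seed.
    """
    docs = list(docs)
    y = np.asarray(labels, dtype=int)
    if len(docs) != len(y):
        raise ValueError("docs and labels must have the same length")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present to fit the label model")

    vectorizer = CountVectorizer(analyzer=ngrams)
    x = vectorizer.fit_transform(docs)
    vocabulary = vectorizer.get_feature_names_out().tolist()

    idx_work, idx_hold = train_test_split(
        np.arange(len(y)),
        test_size=holdout_fraction,
        stratify=y,
        random_state=seed,
    )
    x_work, y_work = x[idx_work], y[idx_work]

    n_folds = min(folds, int(np.bincount(y_work).min()))
    best_c, best_loss = None, np.inf
    if n_folds >= 2:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for c in l1_grid:
            losses = []
            for tr, va in skf.split(x_work, y_work):
                if len(np.unique(y_work[tr])) < 2:
                    continue
                lr = _fit_lasso(x_work[tr], y_work[tr], c, seed)
                p = lr.predict_proba(x_work[va])[:, 1]
                losses.append(log_loss(y_work[va], p, labels=[0, 1]))
            mean_loss = float(np.mean(losses))
            if mean_loss < best_loss - 1e-12:
                best_c, best_loss = c, mean_loss
    if best_c is None:
        best_c = l1_grid[len(l1_grid) // 2]

    held = _fit_lasso(x_work, y_work, best_c, seed)
    p_hold = held.predict_proba(x[idx_hold])[:, 1]
    y_hold = y[idx_hold]
    pred_hold = (p_hold >= 0.5).astype(int)
    metrics = {
        "holdout_n": int(len(idx_hold)),
        "holdout_auc": float(roc_auc_score(y_hold, p_hold))
        if len(np.unique(y_hold)) == 2
        else None,
        "holdout_sensitivity": float(
            np.mean(pred_hold[y_hold == 1]) if (y_hold == 1).any() else np.nan
        ),
        "holdout_specificity": float(
            np.mean(1 - pred_hold[y_hold == 0]) if (y_hold == 0).any() else np.nan
        ),
        "chosen_c": float(best_c),
    }

    final = _fit_lasso(x, y, best_c, seed)
    return NgramLabelModel(
        vocabulary=vocabulary,
        coefficients=final.coef_.ravel(),
        intercept=float(final.intercept_[0]),
        c=float(best_c),
        metrics=metrics,
    )
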