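"""Contrastive-embedding drug-response classifier (scASTRAL-style).

Cells are represented by CPM expression of a marker-gene panel (default 374
genes) rescaled with a tf-idf transformation (genes as terms, cells as
documents).  A contrastive autoencoder (panel -> 64 -> 32, ReLU, mirrored
decoder) embeds cells so that same-class pairs are close and different-class
pairs far in cosine distance; the loss is a weighted sum of the cosine
embedding loss, the reconstruction error and a latent-norm regularizer.  A
cosine-kernel SVM (C = 100, probability-calibrated) on the 32-d embedding
predicts per-cell response; cells whose best class probability does not exceed
0.75 are "undetermined".  Training splits cells class-stratified into 5
batches, trains one model per batch, and keeps the model with the best
accuracy on its left-out cells.

The module also provides permutation feature importance (mean AUROC drop over
repeated shuffles of one panel gene) and a random-panel Monte-Carlo benchmark
comparing the marker panel against size-matched random gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.metrics.pairwise import cosine_similarity
from sklearn.svm import SVC

from sclineage.matrix import CountMatrix

CLASSES = ("sensitive", "tolerant")  # index 0 / 1; "tolerant" is the positive class
PROBABILITY_THRESHOLD = 0.75


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    """Layer widths of the autoencoder; the decoder mirrors the encoder."""

    hidden: int = 64
    latent: int = 32


@dataclass
class TrainConfig:
    n_batches: int = 5
    learning_rate: float = 1e-4
    max_epochs: int = 250
    patience: int = 20
    minibatch: int = 64
    w_cos: float = 1.0
    w_rec: float = 1.0
    w_lat: float = 0.01
    margin: float = 0.0
    svm_c: float = 100.0
    val_frac: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if min(self.w_cos, self.w_rec, self.w_lat) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def cpm_normalize(counts: np.ndarray) -> np.ndarray:
    """Counts-per-million per cell (genes x cells)."""
    total = counts.sum(axis=0).astype(float)
    if (total == 0).any():
        raise ValueError("cell with zero total count")
    return counts * (1e6 / total)[None, :]


def tf_vector(panel_counts: np.ndarray) -> np.ndarray:
    """Panel-restricted count share per cell (genes x cells -> same shape).

    All-zero cells map to all-zero vectors rather than NaN.
    """
    total = panel_counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tf = np.where(total > 0, panel_counts / np.maximum(total, 1e-300), 0.0)
    return tf


def idf_weights(panel_counts: np.ndarray) -> np.ndarray:
    """idf(g) = ln(N_cells / (1 + cells expressing g)) over the panel matrix."""
    n_cells = panel_counts.shape[1]
    n_expr = (panel_counts > 0).sum(axis=1)
    return np.log(n_cells / (1.0 + n_expr))


def tfidf_rescale(panel_counts: np.ndarray, idf: Optional[np.ndarray] = None) -> np.ndarray:
    """tf x idf rescaling of a panel-restricted matrix (genes x cells).

    Pass a frozen ``idf`` (from training) to score new cells consistently.
    """
    if idf is None:
        idf = idf_weights(panel_counts)
    return tf_vector(panel_counts) * idf[:, None]


def cut_to_panel(counts: np.ndarray, gene_ids: pd.Index, panel: Sequence[str]) -> np.ndarray:
    """Restrict a genes x cells matrix to the panel, in panel order.

    Panel genes absent from the matrix are imputed as all-zero rows (warned).
    """
    idx = gene_ids.get_indexer(list(panel))
    out = np.zeros((len(panel), counts.shape[1]))
    present = idx >= 0
    out[present] = counts[idx[present]]
    if not present.all():
        import warnings

        warnings.warn(f"{(~present).sum()} panel genes absent; imputed as zero")
    return out


# ---------------------------------------------------------------------------
# Contrastive pairs and loss
# ---------------------------------------------------------------------------

def build_pairs(labels: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One positive and one negative partner per cell: exactly 2n pairs.

    Returns (first index, second index, pair label in {+1, -1}).  Positive
    partners are uniform over the same class excluding the cell itself (a cell
    alone in its class pairs with itself); negative partners are uniform over
    the other class.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to build pairs")
    idx_of = {c: np.flatnonzero(labels == c) for c in classes}
    i1, i2, y = [], [], []
    for i, lab in enumerate(labels):
        same = idx_of[lab]
        if len(same) > 1:
            j = i
            while j == i:
                j = same[rng.integers(0, len(same))]
        else:
            j = i
        i1.append(i); i2.append(int(j)); y.append(1)
        other = np.concatenate([idx_of[c] for c in classes if c != lab])
        i1.append(i); i2.append(int(other[rng.integers(0, len(other))])); y.append(-1)
    return np.array(i1), np.array(i2), np.array(y)


def cosine_embedding_loss(z1: np.ndarray, z2: np.ndarray, pair_label: np.ndarray,
                          margin: float = 0.0) -> np.ndarray:
    """Per-pair cosine embedding loss: 1 - cos for +1, max(0, cos - margin) for -1.

    Zero-norm latent vectors contribute 0 by convention.
    """
    n1 = np.linalg.norm(z1, axis=1)
    n2 = np.linalg.norm(z2, axis=1)
    ok = (n1 > 0) & (n2 > 0)
    cos = np.zeros(len(z1))
    cos[ok] = np.einsum("ij,ij->i", z1[ok], z2[ok]) / (n1[ok] * n2[ok])
    loss = np.where(pair_label > 0, 1.0 - cos, np.maximum(0.0, cos - margin))
    loss[~ok] = 0.0
    return loss


def contrastive_loss(z1, z2, pair_label, x, x_hat, cfg: TrainConfig) -> float:
    """Weighted three-term loss: cosine embedding + reconstruction + latent norm."""
    l_cos = cosine_embedding_loss(z1, z2, pair_label, cfg.margin).mean()
    l_rec = float(np.mean((x_hat - x) ** 2))
    z = np.vstack([z1, z2])
    l_lat = float(np.mean((z ** 2).sum(axis=1)))
    return cfg.w_cos * l_cos + cfg.w_rec * l_rec + cfg.w_lat * l_lat


# ---------------------------------------------------------------------------
# Autoencoder (numpy, hand-written gradients, Adam)
# ---------------------------------------------------------------------------

class ContrastiveAutoencoder:
    """Input -> hidden -> latent encoder with ReLU and a mirrored decoder."""

    def __init__(self, n_input: int, cfg: EncoderConfig, rng: np.random.Generator):
        def he(shape):
            return rng.normal(0.0, np.sqrt(2.0 / shape[0]), size=shape)

        h, z = cfg.hidden, cfg.latent
        self.params = {
            "W1": he((n_input, h)), "b1": np.zeros(h),
            "W2": he((h, z)), "b2": np.zeros(z),
            "W3": he((z, h)), "b3": np.zeros(h),
            "W4": he((h, n_input)), "b4": np.zeros(n_input),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward ---------------------------------------------------------
    def encode(self, X: np.ndarray) -> np.ndarray:
        p = self.params
        h1 = np.maximum(X @ p["W1"] + p["b1"], 0.0)
        return np.maximum(h1 @ p["W2"] + p["b2"], 0.0)

    def _forward(self, X):
        p = self.params
        a1 = X @ p["W1"] + p["b1"]; h1 = np.maximum(a1, 0.0)
        a2 = h1 @ p["W2"] + p["b2"]; z = np.maximum(a2, 0.0)
        a3 = z @ p["W3"] + p["b3"]; h3 = np.maximum(a3, 0.0)
        xh = h3 @ p["W4"] + p["b4"]
        return a1, h1, a2, z, a3, h3, xh

    # -- loss + gradients on a set of pairs ------------------------------
    def loss_and_grads(self, X: np.ndarray, i1: np.ndarray, i2: np.ndarray,
                       pair_label: np.ndarray, cfg: TrainConfig):
        p = self.params
        a1, h1, a2, z, a3, h3, xh = self._forward(X)
        n_samp, n_in = X.shape
        n_pairs = len(i1)

        z1, z2 = z[i1], z[i2]
        l_cos_vec = cosine_embedding_loss(z1, z2, pair_label, cfg.margin)
        l_rec = np.mean((xh - X) ** 2)
        l_lat = np.mean((z ** 2).sum(axis=1))
        loss = cfg.w_cos * l_cos_vec.mean() + cfg.w_rec * l_rec + cfg.w_lat * l_lat

        # d loss / d xh  (reconstruction)
        dxh = cfg.w_rec * 2.0 * (xh - X) / (n_samp * n_in)
        # d loss / d z: latent norm term
        dz = cfg.w_lat * 2.0 * z / n_samp
        # cosine term
        n1 = np.linalg.norm(z1, axis=1); n2 = np.linalg.norm(z2, axis=1)
        ok = (n1 > 0) & (n2 > 0)
        cos = np.zeros(n_pairs)
        cos[ok] = np.einsum("ij,ij->i", z1[ok], z2[ok]) / (n1[ok] * n2[ok])
        # dcos/dz1 = z2/(n1 n2) - cos * z1 / n1^2  (and symmetrically)
        coef = np.zeros(n_pairs)
        coef[pair_label > 0] = -1.0                        # d(1 - cos)
        neg_active = (pair_label < 0) & (cos > cfg.margin)  # d max(0, cos - m)
        coef[neg_active] = 1.0
        coef *= cfg.w_cos / n_pairs
        coef[~ok] = 0.0
        safe1 = np.where(n1 > 0, n1, 1.0); safe2 = np.where(n2 > 0, n2, 1.0)
        dz1 = coef[:, None] * (z2 / (safe1 * safe2)[:, None] - cos[:, None] * z1 / (safe1 ** 2)[:, None])
        dz2 = coef[:, None] * (z1 / (safe1 * safe2)[:, None] - cos[:, None] * z2 / (safe2 ** 2)[:, None])
        np.add.at(dz, i1, dz1)
        np.add.at(dz, i2, dz2)

        # backprop decoder
        dh3 = dxh @ p["W4"].T
        da3 = dh3 * (a3 > 0)
        dz += da3 @ p["W3"].T
        # backprop encoder
        da2 = dz * (a2 > 0)
        dh1 = da2 @ p["W2"].T
        da1 = dh1 * (a1 > 0)

        grads = {
            "W4": h3.T @ dxh, "b4": dxh.sum(axis=0),
            "W3": z.T @ da3, "b3": da3.sum(axis=0),
            "W2": h1.T @ da2, "b2": da2.sum(axis=0),
            "W1": X.T @ da1, "b1": da1.sum(axis=0),
        }
        return float(loss), grads

    def adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1 ** t)
            vhat = self._adam_v[k] / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        self.params = {k: v.copy() for k, v in state.items()}


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class FittedScastral:
    """Trained encoder + calibrated SVM + panel + frozen idf weights."""

    encoder_state: dict
    encoder_cfg: EncoderConfig
    svm: object  # SVC or CalibratedClassifierCV wrapper
    panel: tuple[str, ...]
    idf: np.ndarray
    selection_accuracy: float
    train_cfg: TrainConfig

    def _encoder(self) -> ContrastiveAutoencoder:
        ae = ContrastiveAutoencoder(len(self.panel), self.encoder_cfg,
                                    np.random.default_rng(0))
        ae.load_state_dict(self.encoder_state)
        return ae

    def embed_counts(self, counts: np.ndarray, gene_ids: pd.Index) -> np.ndarray:
        """Raw counts (genes x cells) -> CPM -> panel -> tf-idf -> embedding."""
        cpm = cpm_normalize(np.asarray(counts, dtype=float))
        panel_cpm = cut_to_panel(cpm, gene_ids, self.panel)
        X = tfidf_rescale(panel_cpm, idf=self.idf).T  # cells x panel
        return self._encoder().encode(X)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "FittedScastral":
        return joblib.load(path)


def _stratified_batches(labels: np.ndarray, n_batches: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Assign each cell a batch id, class-stratified, sizes as equal as possible."""
    batch = np.empty(len(labels), dtype=int)
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        batch[idx] = np.arange(len(idx)) % n_batches
    return batch


def _fit_svm(emb: np.ndarray, y: np.ndarray, c: float, probability: bool,
             seed: int):
    """Cosine-kernel SVM; Platt-style sigmoid calibration when probability=True."""
    svm = SVC(kernel=cosine_similarity, C=c, random_state=seed)
    if not probability:
        svm.fit(emb, y)
        return svm
    counts = np.unique(y, return_counts=True)[1]
    cv = int(min(3, counts.min()))
    if cv < 2:
        raise ValueError("need at least 2 cells per class for calibration")
    cal = CalibratedClassifierCV(svm, method="sigmoid", cv=cv, ensemble=False)
    cal.fit(emb, y)
    return cal


def _train_one_batch(X: np.ndarray, y: np.ndarray, enc_cfg: EncoderConfig,
                     cfg: TrainConfig, rng: np.random.Generator
                     ) -> ContrastiveAutoencoder:
    """Train the autoencoder on one batch with early stopping.

    A stratified 10% of the batch's cells is held out; improvement is a drop
    in validation loss or a rise in validation SVM accuracy, with patience 20.
    """
    n = len(y)
    val = np.zeros(n, dtype=bool)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) >= 2:
            n_val = max(1, int(round(cfg.val_frac * len(idx))))
            n_val = min(n_val, len(idx) - 1)
            val[rng.choice(idx, size=n_val, replace=False)] = True
    if np.unique(y[~val]).size < 2 or np.unique(y[val]).size < 2:
        # batch too small for a stratified split: validate on the training cells
        val[:] = True

    tr_idx = np.flatnonzero(~val) if not val.all() else np.arange(n)
    va_idx = np.flatnonzero(val)
    i1t, i2t, yt = build_pairs(y[tr_idx], rng)
    i1v, i2v, yv = build_pairs(y[va_idx], rng)

    ae = ContrastiveAutoencoder(X.shape[1], enc_cfg, rng)
    Xt, Xv = X[tr_idx], X[va_idx]

    best_loss = np.inf
    best_acc = -np.inf
    best_state = ae.state_dict()
    stall = 0
    n_pairs = len(i1t)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, cfg.minibatch):
            sel = order[start:start + cfg.minibatch]
            _, grads = ae.loss_and_grads(Xt, i1t[sel], i2t[sel], yt[sel], cfg)
            ae.adam_step(grads, cfg.learning_rate)

        val_loss, _ = ae.loss_and_grads(Xv, i1v, i2v, yv, cfg)
        emb_tr = ae.encode(Xt)
        emb_va = ae.encode(Xv)
        try:
            svm = _fit_svm(emb_tr, y[tr_idx], cfg.svm_c, probability=False, seed=cfg.seed)
            acc = float(np.mean(svm.predict(emb_va) == y[va_idx]))
        except ValueError:
            acc = 0.0

        improved = (val_loss < best_loss - 1e-9) or (acc > best_acc + 1e-9)
        if val_loss < best_loss - 1e-9 or acc > best_acc + 1e-9:
            best_state = ae.state_dict()
        best_loss = min(best_loss, val_loss)
        best_acc = max(best_acc, acc)
        stall = 0 if improved else stall + 1
        if stall >= cfg.patience:
            break
    ae.load_state_dict(best_state)
    return ae


def train(counts: np.ndarray, gene_ids: pd.Index, labels: Sequence[str],
          panel: Sequence[str], enc_cfg: Optional[EncoderConfig] = None,
          cfg: Optional[TrainConfig] = None) -> FittedScastral:
    """Train the full classifier on labelled cells.

    ``counts`` is the raw genes x cells matrix over the full gene universe;
    ``labels`` per cell in {"tolerant", "sensitive"}.  Cells are split
    class-stratified into ``n_batches`` batches; one contrastive model + SVM
    is trained per batch and scored on the cells of the other batches; the
    best-scoring model is returned with its selection accuracy.
    """
    enc_cfg = enc_cfg or EncoderConfig()
    cfg = cfg or TrainConfig()
    cfg.validate()
    labels = np.asarray(labels)
    for cls in CLASSES:
        if (labels == cls).sum() < cfg.n_batches:
            raise ValueError(f"need at least {cfg.n_batches} cells of class {cls!r}")

    cpm = cpm_normalize(np.asarray(counts, dtype=float))
    panel_cpm = cut_to_panel(cpm, gene_ids, panel)
    idf = idf_weights(panel_cpm)
    X = tfidf_rescale(panel_cpm, idf=idf).T  # cells x panel

    rng = np.random.default_rng(cfg.seed)
    batch = _stratified_batches(labels, cfg.n_batches, rng)

    candidates = []
    for b in range(cfg.n_batches):
        in_b = batch == b
        ae = _train_one_batch(X[in_b], labels[in_b], enc_cfg, cfg, rng)
        emb_b = ae.encode(X[in_b])
        svm = _fit_svm(emb_b, labels[in_b], cfg.svm_c, probability=True, seed=cfg.seed)
        emb_out = ae.encode(X[~in_b])
        acc = float(np.mean(svm.predict(emb_out) == labels[~in_b]))
        candidates.append((acc, b, ae, svm))

    acc, _, ae, svm = max(candidates, key=lambda t: (t[0], -t[1]))
    return FittedScastral(
        encoder_state=ae.state_dict(),
        encoder_cfg=enc_cfg,
        svm=svm,
        panel=tuple(panel),
        idf=idf,
        selection_accuracy=acc,
        train_cfg=cfg,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    """Per-cell classes/probabilities and per-sample fractions."""

    cells: pd.DataFrame          # class, probability (best-class), p_tolerant
    fractions: pd.Series         # tolerant / sensitive / undetermined, sums to 1

    @property
    def fraction_tolerant(self) -> float:
        return float(self.fractions["tolerant"])


def predict(model: FittedScastral, counts: np.ndarray, gene_ids: pd.Index,
            cell_ids: Optional[Sequence[str]] = None,
            threshold: float = PROBABILITY_THRESHOLD) -> Prediction:
    """Classify cells; probabilities <= ``threshold`` are undetermined.

    Fractions are over all cells — undetermined cells stay in the denominator.
    """
    emb = model.embed_counts(counts, gene_ids)
    proba = model.svm.predict_proba(emb)
    classes = np.asarray(model.svm.classes_)
    best = proba.argmax(axis=1)
    best_p = proba[np.arange(len(best)), best]
    call = np.where(best_p > threshold, classes[best], "undetermined")
    p_tol = proba[:, list(classes).index("tolerant")]
    idx = pd.Index(cell_ids) if cell_ids is not None else pd.RangeIndex(len(best))
    cells = pd.DataFrame(
        {"class": call, "probability": best_p, "p_tolerant": p_tol}, index=idx
    )
    frac = pd.Series(
        {c: float(np.mean(call == c)) for c in ("tolerant", "sensitive", "undetermined")}
    )
    return Prediction(cells=cells, fractions=frac)


def predict_matrix(model: FittedScastral, m: CountMatrix,
                   threshold: float = PROBABILITY_THRESHOLD) -> Prediction:
    return predict(model, m.counts, m.gene_ids, m.cell_ids, threshold)


def predict_pseudobulk(model: FittedScastral, counts: np.ndarray,
                       gene_ids: pd.Index,
                       threshold: float = PROBABILITY_THRESHOLD) -> Prediction:
    """Sum counts across cells and score the pseudobulk profile as one cell.

    The idf weights frozen at training keep single cells and pseudobulk on the
    same scale.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] == 0:
        raise ValueError("pseudobulk input needs at least one cell")
    bulk = counts.sum(axis=1, keepdims=True)
    return predict(model, bulk, gene_ids, ["pseudobulk"], threshold)


# ---------------------------------------------------------------------------
# Permutation feature importance
# ---------------------------------------------------------------------------

def pfi(model: FittedScastral, counts: np.ndarray, gene_ids: pd.Index,
        labels: Sequence[str], n_rep: int = 1000, seed: int = 0) -> pd.Series:
    """Mean AUROC drop per panel gene over ``n_rep`` shuffles.

    The shuffle permutes one gene's tf-idf values across cells before
    encoding; importance is baseline AUROC minus the mean shuffled AUROC.
    """
    labels = np.asarray(labels)
    y = (labels == "tolerant").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")

    cpm = cpm_normalize(np.asarray(counts, dtype=float))
    panel_cpm = cut_to_panel(cpm, gene_ids, model.panel)
    X = tfidf_rescale(panel_cpm, idf=model.idf).T  # cells x panel
    enc = model._encoder()
    tol_col = list(model.svm.classes_).index("tolerant")

    def auroc(Xm: np.ndarray) -> float:
        p = model.svm.predict_proba(enc.encode(Xm))[:, tol_col]
        return roc_auc_score(y, p)

    baseline = auroc(X)
    root = np.random.SeedSequence(seed)
    n_cells, n_panel = X.shape
    drops = np.zeros(n_panel)
    gene_seeds = root.spawn(n_panel)
    for g in range(n_panel):
        rng = np.random.default_rng(gene_seeds[g])
        acc = 0.0
        for _ in range(n_rep):
            Xp = X.copy()
            Xp[:, g] = Xp[rng.permutation(n_cells), g]
            acc += baseline - auroc(Xp)
        drops[g] = acc / n_rep
    return pd.Series(drops, index=list(model.panel), name="pfi")


# ---------------------------------------------------------------------------
# Random-panel Monte-Carlo benchmark
# ---------------------------------------------------------------------------

def random_panel_benchmark(train_counts: np.ndarray, gene_ids: pd.Index,
                           train_labels: Sequence[str],
                           eval_samples: Sequence[np.ndarray],
                           eval_truth: Sequence[float],
                           true_panel: Sequence[str],
                           panel_size: Optional[int] = None,
                           n_sim: int = 100, seed: int = 0,
                           enc_cfg: Optional[EncoderConfig] = None,
                           cfg: Optional[TrainConfig] = None) -> dict:
    """Compare the marker panel against random size-matched gene panels.

    For each simulation a random panel is drawn, a classifier trained, every
    evaluation sample scored, and the Spearman rank correlation between the
    predicted tolerant fractions and the ground-truth tolerance recorded.
    Returns ``{"true_score", "random_scores", "percentile"}``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    panel_size = panel_size or len(true_panel)
    if panel_size > len(gene_ids):
        raise ValueError("panel_size exceeds the number of genes")
    cfg = cfg or TrainConfig()

    def score_panel(panel, train_seed) -> float:
        local = TrainConfig(**{**cfg.__dict__, "seed": train_seed})
        model = train(train_counts, gene_ids, train_labels, panel,
                      enc_cfg=enc_cfg, cfg=local)
        fracs = [predict(model, s, gene_ids).fraction_tolerant for s in eval_samples]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho = stats.spearmanr(fracs, eval_truth).statistic
        # a panel predicting a constant fraction has no rank correlation:
        # score it 0 (no predictive power) rather than NaN
        return float(rho) if np.isfinite(rho) else 0.0

    true_score = score_panel(list(true_panel), cfg.seed)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_sim)
    for i in range(n_sim):
        panel = list(gene_ids[rng.choice(len(gene_ids), size=panel_size, replace=False)])
        scores[i] = score_panel(panel, int(rng.integers(0, 2**31 - 1)))
    pct = float(np.mean(true_score > scores))
    return {"true_score": true_score, "random_scores": scores, "percentile": pct}
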