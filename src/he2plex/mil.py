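"""Attention-based multiple-instance learning for discrete-time survival and
subtype classification, with optional co-attention multimodal fusion.

Bags are sets of per-patch feature vectors (one bag per patient/slide, one
feature matrix per modality).  Gated attention pooling aggregates instances
into a bag vector; the survival head models per-interval hazards with one
sigmoid neuron per quartile bin and defines the patient risk as the negative
sum of the interval logits.  Evaluation uses the IPCW time-dependent
concordance index, median-split Kaplan–Meier curves and the log-rank test.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.optim import Adam, ReduceLROnPlateau
from .synthetic import SurvivalBag, discretize_by_quartiles

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class GatedAttentionPool(nn.Module):
    """a_i = softmax_i( wᵀ(tanh(V h_i) ⊙ σ(U h_i)) );  g = Σ a_i h_i."""

    def __init__(self, d: int, hidden: int = 64, rng=None):
        rng = rng or np.random.default_rng(0)
        self.v = Tensor(nn.xavier_uniform((d, hidden), d, hidden, rng),
                        requires_grad=True)
        self.u = Tensor(nn.xavier_uniform((d, hidden), d, hidden, rng),
                        requires_grad=True)
        self.w = Tensor(nn.xavier_uniform((hidden, 1), hidden, 1, rng),
                        requires_grad=True)

    def forward(self, h) -> tuple[Tensor, Tensor]:
        h = ag.astensor(h)                       # (N, d)
        gate = ag.mul(ag.tanh(ag.matmul(h, self.v)),
                      ag.sigmoid(ag.matmul(h, self.u)))
        scores = ag.reshape(ag.matmul(gate, self.w), (h.shape[0],))
        a = ag.softmax(scores, axis=0)
        g = ag.matmul(ag.reshape(a, (1, h.shape[0])), h)  # (1, d)
        return ag.reshape(g, (h.shape[1],)), a


class CoAttention(nn.Module):
    """Ĥ = softmax((W_q P)(W_k H)ᵀ / √d) (W_v H): P-guided re-mixing of H."""

    def __init__(self, d: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.wq = Tensor(nn.xavier_uniform((d, d), d, d, rng), requires_grad=True)
        self.wk = Tensor(nn.xavier_uniform((d, d), d, d, rng), requires_grad=True)
        self.wv = Tensor(nn.xavier_uniform((d, d), d, d, rng), requires_grad=True)
        self.d = d

    def forward(self, guide, target) -> tuple[Tensor, Tensor]:
        """`guide` (N, d) attends over `target` (N, d); rows of A sum to 1."""
        guide, target = ag.astensor(guide), ag.astensor(target)
        if guide.shape[1] != self.d or target.shape[1] != self.d:
            raise ValueError("feature dimension mismatch in co-attention")
        q = ag.matmul(guide, ag.transpose(self.wq, None))
        k = ag.matmul(target, ag.transpose(self.wk, None))
        att = ag.softmax(ag.matmul(q, ag.transpose(k, None))
                         * (1.0 / np.sqrt(self.d)), axis=1)
        v = ag.matmul(target, ag.transpose(self.wv, None))
        return ag.matmul(att, v), att


def coattention(h: np.ndarray, p: np.ndarray, wq: np.ndarray, wk: np.ndarray,
                wv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Functional form (P guides H): returns (Ĥ, A_{P→H})."""
    mod = CoAttention(h.shape[1])
    mod.wq, mod.wk, mod.wv = Tensor(wq), Tensor(wk), Tensor(wv)
    out, att = mod(ag.astensor(p), ag.astensor(h))
    return out.data, att.data


def gated_attention_pool(instances: np.ndarray, v: np.ndarray, u: np.ndarray,
                         w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Functional form of the gated-attention pooling."""
    pool = GatedAttentionPool(instances.shape[1], v.shape[1])
    pool.v, pool.u, pool.w = Tensor(v), Tensor(u), Tensor(w.reshape(-1, 1))
    g, a = pool(instances)
    return g.data, a.data


# ---------------------------------------------------------------------------
# survival head and losses
# ---------------------------------------------------------------------------

def hazards_and_survival(logits) -> tuple[Tensor, Tensor]:
    """Discrete hazards h_j = σ(logit_j) and S(j) = Π_{k≤j}(1 − h_k)."""
    logits = ag.astensor(logits)
    h = ag.sigmoid(logits)
    j = h.shape[-1]
    # cumulative product via lower-triangular mask on log(1 − h)
    log1m = ag.tlog(1.0 - h + 1e-12)
    tri = Tensor(np.tril(np.ones((j, j))))
    if h.ndim == 1:
        logs = ag.matmul(tri, ag.reshape(log1m, (j, 1)))
        surv = ag.texp(ag.reshape(logs, (j,)))
    else:
        surv = ag.texp(ag.matmul(log1m, ag.transpose(tri, None)))
    return h, surv


def risk_score(logits) -> float:
    """Patient-level risk: negative sum of the discrete survival function.

    High per-interval hazards shrink S(j), pushing the risk towards 0 (its
    maximum), so higher risk means earlier expected death — the orientation
    the concordance index and KM risk groups assume.  (The negative sum of
    the raw interval logits has the opposite orientation and would be
    anti-concordant with observed event times.)
    """
    with ag.no_grad():
        _, surv = hazards_and_survival(ag.astensor(logits).detach())
    return float(-np.sum(surv.data))


def survival_nll(logits, y_bin: int, censor: int) -> Tensor:
    """Discrete-time survival negative log-likelihood for one patient.

    censor = 0 when death is observed.  Uncensored patients contribute
    −log S(y−1) − log h(y); censored patients contribute −log S(y).
    S(0-th index −1) = 1 by convention (empty product).
    """
    logits = ag.astensor(logits)
    j = logits.shape[-1]
    if not (0 <= y_bin < j):
        raise ValueError("time bin out of range")
    h, surv = hazards_and_survival(logits)
    one_hot = np.zeros(j)
    one_hot[y_bin] = 1.0
    s_y = ag.tsum(ag.mul(surv, Tensor(one_hot)))
    h_y = ag.tsum(ag.mul(h, Tensor(one_hot)))
    if y_bin > 0:
        prev = np.zeros(j)
        prev[y_bin - 1] = 1.0
        s_prev = ag.tsum(ag.mul(surv, Tensor(prev)))
    else:
        s_prev = Tensor(1.0)
    if censor:
        return ag.neg(ag.tlog(s_y + 1e-12))
    return ag.neg(ag.tlog(s_prev + 1e-12)) + ag.neg(ag.tlog(h_y + 1e-12))


def cohort_survival_nll(logits_list, bins, censors) -> Tensor:
    total = None
    for lg, yb, c in zip(logits_list, bins, censors):
        term = survival_nll(lg, int(yb), int(c))
        total = term if total is None else total + term
    return total


def ce_loss(logits, label: int) -> Tensor:
    """Multiclass cross-entropy −Σ_k y_k log ŷ_k with softmax probabilities."""
    logits = ag.astensor(logits)
    k = logits.shape[-1]
    p = ag.softmax(logits, axis=-1)
    one_hot = np.zeros(k)
    one_hot[label] = 1.0
    return ag.neg(ag.tlog(ag.tsum(ag.mul(p, Tensor(one_hot))) + 1e-12))


def discretize_times(times, cuts=None):
    """Quartile binning (train cuts reusable on held-out data)."""
    return discretize_by_quartiles(times, cuts)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MilConfig:
    feature_dim: int = 512
    hidden: int = 64
    n_out: int = 4               # J survival bins or K classes
    mode: str = "unimodal"       # or "multimodal"
    task: str = "survival"       # or "subtype"
    seed: int = 0


class MilModel(nn.Module):
    def __init__(self, cfg: MilConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.feature_dim
        if cfg.mode == "multimodal":
            self.coatt_h = CoAttention(d, rng)   # P guides H
            self.coatt_p = CoAttention(d, rng)   # H guides P
            self.pool_h = GatedAttentionPool(d, cfg.hidden, rng)
            self.pool_p = GatedAttentionPool(d, cfg.hidden, rng)
            self.fuse = nn.Linear(2 * d, d, rng=rng)
        else:
            self.pool_h = GatedAttentionPool(d, cfg.hidden, rng)
        self.head = nn.Linear(d, cfg.n_out, rng=rng)

    def forward(self, features_h, features_p=None) -> Tensor:
        if self.cfg.mode == "multimodal":
            if features_p is None:
                raise ValueError("multimodal model needs both modalities")
            h_hat, _ = self.coatt_h(ag.astensor(features_p), ag.astensor(features_h))
            p_hat, _ = self.coatt_p(ag.astensor(features_h), ag.astensor(features_p))
            gh, _ = self.pool_h(h_hat)
            gp, _ = self.pool_p(p_hat)
            g = ag.concat([gh, gp], axis=0)
            g = ag.relu(self.fuse(ag.reshape(g, (1, g.shape[0]))))
            logits = self.head(g)
        else:
            g, _ = self.pool_h(ag.astensor(features_h))
            logits = self.head(ag.reshape(g, (1, g.shape[0])))
        return ag.reshape(logits, (self.cfg.n_out,))


def fuse_and_predict(model: MilModel, bag: SurvivalBag) -> dict:
    """Run one bag through the model; returns logits, risk and class argmax."""
    fp = bag.features_p if model.cfg.mode == "multimodal" else None
    with ag.no_grad():
        logits = model(bag.features_h, fp)
    return {"logits": logits.data.copy(), "risk": risk_score(logits),
            "label": int(np.argmax(logits.data))}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_mil(bags: list[SurvivalBag], cfg: MilConfig, epochs: int = 30,
              lr: float = 1e-4, val_fraction: float = 0.2, patience: int = 10,
              seed: int = 0) -> tuple[MilModel, dict]:
    """Batch-1 Adam training with early stopping on the validation loss."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(bags))
    n_val = max(1, int(val_fraction * len(bags)))
    val_idx = set(order[:n_val].tolist())
    train_bags = [b for i, b in enumerate(bags) if i not in val_idx]
    val_bags = [b for i, b in enumerate(bags) if i in val_idx]

    model = MilModel(cfg)
    params = model.parameters()
    opt = Adam(params, lr=lr)
    sched = ReduceLROnPlateau(opt, patience=max(2, patience // 3))
    best_val = np.inf
    best_state = model.state_arrays()
    bad = 0
    history = {"train_loss": [], "val_loss": []}

    def bag_loss(bag: SurvivalBag) -> Tensor:
        fp = bag.features_p if cfg.mode == "multimodal" else None
        logits = model(bag.features_h, fp)
        if cfg.task == "survival":
            return survival_nll(logits, bag.time_bin, bag.censor)
        return ce_loss(logits, bag.label)

    for epoch in range(epochs):
        rng.shuffle(train_bags)
        tr_losses = []
        for bag in train_bags:
            loss = bag_loss(bag)
            grads = ag.grad(loss, params)
            opt.step(grads)
            tr_losses.append(float(loss.data))
        with ag.no_grad():
            val_losses = [float(bag_loss(b).data) for b in val_bags]
        vl = float(np.mean(val_losses))
        history["train_loss"].append(float(np.mean(tr_losses)))
        history["val_loss"].append(vl)
        sched.step(vl)
        if vl < best_val - 1e-6:
            best_val, bad = vl, 0
            best_state = model.state_arrays()
        else:
            bad += 1
            if bad > patience:
                log.info("early stopping at epoch %d", epoch)
                break
    model.load_state_arrays(best_state)
    return model, history


def predict_risks(model: MilModel, bags: list[SurvivalBag]) -> np.ndarray:
    return np.array([fuse_and_predict(model, b)["risk"] for b in bags])


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_survival(risks: np.ndarray, times: np.ndarray,
                      censors: np.ndarray,
                      train_times: np.ndarray | None = None,
                      train_censors: np.ndarray | None = None) -> dict:
    """Time-dependent C-index (IPCW), median-split KM curves, log-rank test.

    censor = 0 means the death was observed (event), 1 means censored.
    The censoring distribution for the IPCW estimator is taken from the
    training cohort when given, else from the evaluation cohort.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test
    from sksurv.metrics import concordance_index_ipcw
    from sksurv.util import Surv

    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(censors) == 0
    if events.sum() == 0:
        raise ValueError("no observed events: survival metrics undefined")
    tr_t = times if train_times is None else np.asarray(train_times, dtype=float)
    tr_e = events if train_censors is None else np.asarray(train_censors) == 0
    surv_train = Surv.from_arrays(event=tr_e, time=tr_t)
    surv_test = Surv.from_arrays(event=events, time=times)
    tau = float(np.quantile(times, 0.9))
    try:
        cindex = float(concordance_index_ipcw(surv_train, surv_test, risks,
                                              tau=tau)[0])
    except ValueError:
        from lifelines.utils import concordance_index
        cindex = float(concordance_index(times, -risks, events))
        log.warning("IPCW estimator failed; fell back to Harrell's C")

    split = np.median(risks)
    high = risks > split
    km = {}
    for name, sel in (("low_risk", ~high), ("high_risk", high)):
        fitter = KaplanMeierFitter()
        if sel.sum():
            fitter.fit(times[sel], event_observed=events[sel], label=name)
            km[name] = fitter
    if high.sum() and (~high).sum():
        lr = logrank_test(times[~high], times[high],
                          event_observed_A=events[~high],
                          event_observed_B=events[high])
        logrank_stat, logrank_p = float(lr.test_statistic), float(lr.p_value)
    else:
        logrank_stat, logrank_p = np.nan, np.nan
    return {"cindex": cindex, "km": km, "logrank_stat": logrank_stat,
            "logrank_p": logrank_p, "risk_split": float(split)}
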