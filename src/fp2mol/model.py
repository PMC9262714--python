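"""Fingerprint-conditioned sequence model with formula countdown.

The model translates a (fingerprint, molecular formula) pair into a SMILES
token sequence. An encoder (batch normalization + two rectified-linear
dense stages) maps the concatenated inputs to a latent code ``z`` and, via
a linear stage, to the initial states of a multi-layer LSTM decoder. At
each step the decoder receives the previous token, the current counter
state ``v`` (remaining atoms per element, remaining hydrogen budget, and
the open-bracket balance) and the constant context ``z``, normalized
batch-wise, and emits a softmax distribution over the token vocabulary.

Hydrogen atoms are not spelled out in a SMILES, so a small auxiliary LSTM
(the hydrogen-count estimator, parameters ``phi``) predicts per-token
"hydrogen equivalents" whose masked sum is trained to match the molecule's
total hydrogen count. Its outputs feed the hydrogen channel of the counter
but are treated as constants by the decoder: the two parameter sets are
optimized concomitantly but separately, and no gradient crosses between
them.

In naive mode the fingerprint input is replaced by zeros, yielding a
generator of formula-compatible structures that is blind to structural
information — the baseline for measuring the value of the fingerprint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .molecules import ELEMENT_INDEX, N_ELEMENTS, FingerprintConfig
from .tokenizer import TokenVocabulary, counter_matrix, onehot

COUNTER_DIM = N_ELEMENTS + 1
H_ROW = ELEMENT_INDEX["H"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and size configuration.

    The default sizes are the desk-scale preset (latent 64, two decoder
    layers of 128 units); ``paper_scale`` restores the full-fidelity sizes
    (latent 256, three layers of 256 units, sequence length 128).
    """

    fp_len: int
    latent_dim: int = 64
    enc_units: int = 256
    dec_layers: int = 2
    dec_units: int = 128
    hcount_layers: int = 2
    hcount_units: int = 32
    max_len: int = 40
    naive_mode: bool = False
    counter_from_labels: bool = False
    seed: int = 0

    @classmethod
    def paper_scale(cls, fp_len: int = 3609, **kw) -> "ModelConfig":
        return cls(fp_len=fp_len, latent_dim=256, enc_units=512,
                   dec_layers=3, dec_units=256, max_len=128, **kw)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (Adam with the standard moment decays)."""

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-7
    seed: int = 0


class GenerativeModel:
    """Encoder–decoder network plus hydrogen-count estimator."""

    def __init__(self, cfg: ModelConfig, vocab: TokenVocabulary,
                 fp_config: FingerprintConfig | None = None):
        self.cfg = cfg
        self.vocab = vocab
        self.fp_config = fp_config or FingerprintConfig()
        self.M = counter_matrix(vocab)  # (11, t+1)
        t = vocab.t
        rng = np.random.default_rng(cfg.seed)
        d_enc = cfg.fp_len + N_ELEMENTS
        d_dec = t + COUNTER_DIM + cfg.latent_dim
        self.theta_modules = {
            "bn_enc": nn.BatchNorm(d_enc),
            "enc1": nn.Dense(rng, d_enc, cfg.enc_units, relu=True),
            "enc2": nn.Dense(rng, cfg.enc_units, cfg.latent_dim, relu=True),
            "enc_state": nn.Dense(rng, cfg.latent_dim,
                                  2 * cfg.dec_layers * cfg.dec_units),
            "bn_dec": nn.BatchNorm(d_dec),
            "dec_lstm": nn.LSTMStack(rng, d_dec, cfg.dec_units, cfg.dec_layers),
            "dec_out": nn.Dense(rng, cfg.dec_units, t),
        }
        self.phi_modules = {
            "hc_lstm": nn.LSTMStack(rng, t, cfg.hcount_units, cfg.hcount_layers),
            "hc_out": nn.Dense(rng, cfg.hcount_units, 1),
        }
        self._special_mask = np.zeros(t, dtype=np.float64)
        for idx in (vocab.start_idx, vocab.stop_idx, vocab.pad_idx):
            self._special_mask[idx] = 1.0

    # ------------------------------------------------------------------
    # components

    def encode(self, x_F: np.ndarray, x_M: np.ndarray, training: bool = False):
        """Latent code z and initial decoder states from the query pair.

        In naive mode the fingerprint is replaced by zeros, so z depends on
        the formula alone.
        """
        x_F = np.atleast_2d(np.asarray(x_F, dtype=np.float64))
        x_M = np.atleast_2d(np.asarray(x_M, dtype=np.float64))
        if x_F.shape[1] != self.cfg.fp_len or x_M.shape[1] != N_ELEMENTS:
            raise ValueError("encoder input shape mismatch")
        if self.cfg.naive_mode:
            x_F = np.zeros_like(x_F)
        m = self.theta_modules
        x = np.concatenate([x_F, x_M], axis=1)
        x = m["bn_enc"].forward(x, training)
        h = m["enc1"].forward(x, cache=training)
        z = m["enc2"].forward(h, cache=training)
        s = m["enc_state"].forward(z, cache=training)
        states = self._unpack_states(s)
        return z, states

    def _unpack_states(self, s: np.ndarray):
        B = s.shape[0]
        L, U = self.cfg.dec_layers, self.cfg.dec_units
        s = s.reshape(B, L, 2, U)
        return [(s[:, li, 0], s[:, li, 1]) for li in range(L)]

    def _pack_state_grads(self, d_init):
        B = d_init[0][0].shape[0]
        L, U = self.cfg.dec_layers, self.cfg.dec_units
        out = np.empty((B, L, 2, U))
        for li, (dh, dc) in enumerate(d_init):
            out[:, li, 0] = dh
            out[:, li, 1] = dc
        return out.reshape(B, L * 2 * U)

    def token_masks(self, Y: np.ndarray):
        """(real-token mask, loss mask) for index sequences Y (B, T).

        Real tokens are everything except start/stop/pad: they feed the
        counter and the hydrogen-sum loss. The loss mask covers predicted
        positions 1..T-1 up to and including the stop token.
        """
        v = self.vocab
        mask_tok = ~np.isin(Y, (v.start_idx, v.stop_idx, v.pad_idx))
        mask_loss = Y[:, 1:] != v.pad_idx
        return mask_tok.astype(np.float64), mask_loss.astype(np.float64)

    def hcount_seq(self, Yoh: np.ndarray, cache: bool = True) -> np.ndarray:
        """Per-token hydrogen-equivalent estimates for one-hot input (B,T,t)."""
        p = self.phi_modules
        H = p["hc_lstm"].forward_seq(Yoh)
        return p["hc_out"].forward(H, cache=cache)[..., 0]

    def counters(self, x_M: np.ndarray, Yoh: np.ndarray,
                 y_H: np.ndarray) -> np.ndarray:
        """Counter states v_0..v_{T-1} for token sequence Yoh with hydrogen
        channel y_H (already masked to real tokens)."""
        t = self.vocab.t
        contrib = Yoh @ self.M[:, :t].T + y_H[..., None] * self.M[:, t]
        v0 = np.concatenate(
            [np.asarray(x_M, dtype=np.float64),
             np.zeros((x_M.shape[0], 1))], axis=1)
        return v0[:, None, :] - np.cumsum(contrib, axis=1)

    # ------------------------------------------------------------------
    # teacher-forced forward / training

    def teacher_forward(self, x_F, x_M, Y, training: bool = False,
                        h_labels: np.ndarray | None = None):
        """Teacher-forced pass; returns a dict with probabilities, masks,
        counters and intermediate values needed for the backward pass."""
        Y = np.asarray(Y)
        B, T = Y.shape
        t = self.vocab.t
        Yoh = onehot(Y, t)
        mask_tok, mask_loss = self.token_masks(Y)
        yH_hat = self.hcount_seq(Yoh, cache=training)
        if self.cfg.counter_from_labels:
            if h_labels is None:
                raise ValueError("counter_from_labels requires h_labels")
            yH_used = np.asarray(h_labels, dtype=np.float64)
        else:
            yH_used = yH_hat
        yH_eff = yH_used * mask_tok
        V = self.counters(np.atleast_2d(x_M), Yoh, yH_eff)
        z, states = self.encode(x_F, x_M, training=training)
        m = self.theta_modules
        z_tile = np.broadcast_to(z[:, None, :], (B, T - 1, z.shape[1]))
        dec_in = np.concatenate([Yoh[:, :-1], V[:, :-1], z_tile], axis=2)
        x = m["bn_dec"].forward(dec_in, training)
        H = m["dec_lstm"].forward_seq(x, states)
        logits = m["dec_out"].forward(H, cache=training)
        probs = nn.softmax(logits)
        return {"probs": probs, "z": z, "V": V, "yH_hat": yH_hat,
                "mask_tok": mask_tok, "mask_loss": mask_loss, "Yoh": Yoh}

    def losses(self, out: dict, Y: np.ndarray, h_tot: np.ndarray):
        """(cross-entropy, hydrogen loss, token accuracy) from a forward pass."""
        probs, mask = out["probs"], out["mask_loss"]
        B, Tm1, t = probs.shape
        target = Y[:, 1:]
        p_t = np.take_along_axis(probs, target[..., None], axis=2)[..., 0]
        n_mask = mask.sum()
        ce = float(-(np.log(np.maximum(p_t, 1e-300)) * mask).sum() / n_mask)
        acc = float(((probs.argmax(axis=2) == target) * mask).sum() / n_mask)
        h_sum = (out["yH_hat"] * out["mask_tok"]).sum(axis=1)
        h_loss = float(np.mean((h_sum - h_tot) ** 2))
        return ce, h_loss, acc

    def train_step(self, x_F, x_M, Y, h_tot, opt_theta: nn.Adam,
                   opt_phi: nn.Adam):
        """One teacher-forced gradient step on a batch; returns metrics."""
        Y = np.asarray(Y)
        B = Y.shape[0]
        out = self.teacher_forward(x_F, x_M, Y, training=True)
        ce, h_loss, acc = self.losses(out, Y, h_tot)

        m, p = self.theta_modules, self.phi_modules
        nn.zero_grads(m)
        nn.zero_grads(p)

        # decoder loss -> theta
        probs, mask = out["probs"], out["mask_loss"]
        target_oh = onehot(Y[:, 1:], self.vocab.t)
        n_mask = mask.sum()
        dlogits = (probs - target_oh) * mask[..., None] / n_mask
        dH = m["dec_out"].backward(dlogits)
        dx, d_init = m["dec_lstm"].backward_seq(dH)
        d_in = m["bn_dec"].backward(dx)
        t = self.vocab.t
        dz = d_in[:, :, t + COUNTER_DIM :].sum(axis=1)
        dz += m["enc_state"].backward(self._pack_state_grads(d_init))
        dh = m["enc2"].backward(dz)
        d_enc_in = m["enc1"].backward(dh)
        m["bn_enc"].backward(d_enc_in)

        # hydrogen loss -> phi (independent of the decoder loss)
        h_sum = (out["yH_hat"] * out["mask_tok"]).sum(axis=1)
        dyH = (2.0 * (h_sum - h_tot) / B)[:, None] * out["mask_tok"]
        dHc = p["hc_out"].backward(dyH[..., None])
        p["hc_lstm"].backward_seq(dHc)

        opt_theta.step(nn.collect_params(m), nn.collect_grads(m))
        opt_phi.step(nn.collect_params(p), nn.collect_grads(p))
        return {"ce": ce, "h_loss": h_loss, "acc": acc}

    def fit(self, x_F_clean: np.ndarray, x_M: np.ndarray, Y: np.ndarray,
            train_cfg: TrainingConfig, simulator=None,
            sim_config=None, log=None) -> list[dict]:
        """Train on tokenized sequences with on-the-fly fingerprint noise.

        ``x_F_clean`` holds clean binary structural fingerprints; if a
        :class:`~fp2mol.simulate.FingerprintSimulator` is given, each batch
        is corrupted into sim-FPs before encoding. Returns the per-epoch
        history (mean cross-entropy, hydrogen loss, token accuracy).
        """
        self.train_config = train_cfg
        rng = np.random.default_rng(train_cfg.seed)
        opt_theta = nn.Adam(train_cfg.learning_rate, train_cfg.beta1,
                            train_cfg.beta2, train_cfg.adam_eps)
        opt_phi = nn.Adam(train_cfg.learning_rate, train_cfg.beta1,
                          train_cfg.beta2, train_cfg.adam_eps)
        N = len(Y)
        h_tot = np.asarray(x_M, dtype=np.float64)[:, H_ROW]
        history = []
        for epoch in range(train_cfg.epochs):
            order = rng.permutation(N)
            sums = {"ce": 0.0, "h_loss": 0.0, "acc": 0.0}
            n_batches = 0
            for lo in range(0, N, train_cfg.batch_size):
                idx = order[lo : lo + train_cfg.batch_size]
                xf = x_F_clean[idx]
                if simulator is not None:
                    xf = simulator.simulate(xf, sim_config, rng=rng)
                metrics = self.train_step(xf, x_M[idx], Y[idx], h_tot[idx],
                                          opt_theta, opt_phi)
                for k in sums:
                    sums[k] += metrics[k]
                n_batches += 1
            rec = {"epoch": epoch}
            rec.update({k: sums[k] / n_batches for k in sums})
            history.append(rec)
            if log is not None:
                log(rec)
        return history

    # ------------------------------------------------------------------
    # stepwise inference API (used by beam search / sampling)

    def init_decode(self, x_F, x_M):
        """Encode one or more queries and build the initial decode state."""
        x_M = np.atleast_2d(np.asarray(x_M, dtype=np.float64))
        z, states = self.encode(x_F, x_M, training=False)
        B = z.shape[0]
        v0 = np.concatenate([x_M, np.zeros((B, 1))], axis=1)
        hc_states = self.phi_modules["hc_lstm"].zero_state(B)
        return z, states, hc_states, v0

    def hcount_step(self, y_idx: np.ndarray, hc_states):
        yoh = onehot(np.asarray(y_idx), self.vocab.t)
        h, hc_states = self.phi_modules["hc_lstm"].step(yoh, hc_states)
        yh = self.phi_modules["hc_out"].forward(h, cache=False)[:, 0]
        return yh, hc_states

    def advance_counter(self, v: np.ndarray, y_idx: np.ndarray,
                        y_H: np.ndarray) -> np.ndarray:
        """Apply the countdown update for chosen tokens (specials neutral)."""
        t = self.vocab.t
        y_idx = np.asarray(y_idx)
        real = 1.0 - self._special_mask[y_idx]
        contrib = self.M[:, :t].T[y_idx] + (y_H * real)[:, None] * self.M[:, t]
        return v - contrib

    def decode_step(self, y_idx: np.ndarray, v: np.ndarray, z: np.ndarray,
                    dec_states):
        """One decoder step in inference mode.

        Returns the next-token probability distribution (B, t) and the
        advanced decoder states.
        """
        m = self.theta_modules
        yoh = onehot(np.asarray(y_idx), self.vocab.t)
        x = np.concatenate([yoh, v, z], axis=1)
        x = m["bn_dec"].forward(x, training=False)
        h, dec_states = m["dec_lstm"].step(x, dec_states)
        logits = m["dec_out"].forward(h, cache=False)
        return nn.softmax(logits), dec_states

    def score_sequences(self, x_F, x_M, Y: np.ndarray) -> np.ndarray:
        """Cumulative log-probability of given sequences (teacher-forced
        re-evaluation in inference mode); the independent check for beam
        search scores."""
        out = self.teacher_forward(x_F, x_M, np.asarray(Y), training=False)
        p_t = np.take_along_axis(
            out["probs"], np.asarray(Y)[:, 1:, None], axis=2)[..., 0]
        logp = np.log(np.maximum(p_t, 1e-300)) * out["mask_loss"]
        return logp.sum(axis=1)

    # ------------------------------------------------------------------
    # checkpointing

    def save(self, path) -> None:
        """Write a single-file checkpoint (parameters + config + vocab)."""
        arrays = {}
        for prefix, mods in (("theta", self.theta_modules),
                             ("phi", self.phi_modules)):
            for k, arr in nn.collect_params(mods).items():
                arrays[f"{prefix}:{k}"] = arr
        for name in ("bn_enc", "bn_dec"):
            bn = self.theta_modules[name]
            arrays[f"state:{name}.moving_mean"] = bn.moving_mean
            arrays[f"state:{name}.moving_var"] = bn.moving_var
        meta = {
            "model_config": asdict(self.cfg),
            "vocab": self.vocab.to_dict(),
            "fp_config": self.fp_config.to_dict(),
            "train_config": (asdict(self.train_config)
                             if getattr(self, "train_config", None) else None),
        }
        arrays["meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "GenerativeModel":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = ModelConfig(**meta["model_config"])
        vocab = TokenVocabulary.from_dict(meta["vocab"])
        fp_cfg = FingerprintConfig.from_dict(meta["fp_config"])
        model = cls(cfg, vocab, fp_cfg)
        for prefix, mods in (("theta", model.theta_modules),
                             ("phi", model.phi_modules)):
            params = nn.collect_params(mods)
            for k, arr in params.items():
                arr[...] = data[f"{prefix}:{k}"]
        for name in ("bn_enc", "bn_dec"):
            bn = model.theta_modules[name]
            bn.moving_mean = data[f"state:{name}.moving_mean"].copy()
            bn.moving_var = data[f"state:{name}.moving_var"].copy()
        return model
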