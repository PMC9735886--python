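"""The trainable sleep-staging network.

Assembles the pieces defined (and unit-tested) as single-sample numpy
reference functions in :mod:`node_attention`, :mod:`temporal_branch` and
:mod:`transition_estimator` into one batched, differentiable model on the
:mod:`mganet.autodiff` engine:

* spatial branch: stacked masked multi-head graph attention over the
  electrode graph on the centre epoch of a context window, optionally
  followed by spatial-domain attention;
* temporal branch (ablation flag A): a GRU over the channel-averaged
  feature sequence of the window, optionally followed by temporal-domain
  attention;
* the two domain attentions are controlled jointly by ablation flag B;
* head: pooled branch features are fused and mapped to stage
  probabilities; with flag C the transitional-stage estimator reweights
  them by a sigmoid stage-attention vector.

Input samples are context windows of ``context_len`` consecutive epochs
(feature shape ``(T, n_channels, n_features)``); the predicted label
belongs to the centre epoch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .channel_graph import ChannelGraph
from .exceptions import ParameterError
from .stages import N_STAGES

__all__ = ["ModelConfig", "AblationFlags", "MganetModel"]


@dataclass(frozen=True)
class AblationFlags:
    """The three ablation switches: A = recurrent temporal branch,
    B = spatial/temporal domain attention, C = transitional-stage
    estimator.  The stacked graph-attention baseline is always present."""

    use_rnn: bool = True
    use_st_attention: bool = True
    use_tse: bool = True

    def variant_name(self) -> str:
        parts = [
            flag
            for flag, on in (
                ("A", self.use_rnn),
                ("B", self.use_st_attention),
                ("C", self.use_tse),
            )
            if on
        ]
        return "baseline" + "".join(f"+{p}" for p in parts) if parts else "baseline"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``n_heads`` defaults to 8 (the optimum of the head-count sweep);
    ``gat_depth`` stacked attention layers of width ``gat_hidden``;
    ``gru_hidden`` temporal state size; ``context_len`` consecutive epochs
    per sample (odd, centred on the scored epoch); ``leaky_slope`` is the
    attention score activation slope.
    """

    n_heads: int = 8
    gat_hidden: int = 16
    gat_depth: int = 2
    gru_hidden: int = 32
    context_len: int = 5
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.context_len < 1 or self.context_len % 2 == 0:
            raise ParameterError("context_len must be a positive odd integer")
        for name in ("n_heads", "gat_hidden", "gat_depth", "gru_hidden"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")


class MganetModel:
    """Batched differentiable model over a fixed electrode graph."""

    def __init__(
        self,
        graph: ChannelGraph,
        n_features: int,
        config: ModelConfig = ModelConfig(),
        flags: AblationFlags = AblationFlags(),
        seed: int = 0,
    ):
        self.graph = graph
        self.n_features = int(n_features)
        self.config = config
        self.flags = flags
        self.mask = graph.adjacency.astype(float)
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(seed))

    # -- parameters --------------------------------------------------------
    def _add(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        n = self.graph.n_nodes
        f_in = self.n_features
        for layer in range(cfg.gat_depth):
            d_in = f_in if layer == 0 else cfg.gat_hidden
            scale = np.sqrt(2.0 / (d_in + cfg.gat_hidden))
            for h in range(cfg.n_heads):
                self._add(f"gat{layer}.h{h}.W", rng.normal(0, scale, (d_in, cfg.gat_hidden)))
                self._add(f"gat{layer}.h{h}.a", rng.normal(0, scale, (2 * cfg.gat_hidden, 1)))
            if layer < cfg.gat_depth - 1:
                self._add(
                    f"inter{layer}.W",
                    rng.normal(0, np.sqrt(1.0 / cfg.gat_hidden), (cfg.gat_hidden, cfg.gat_hidden)),
                )
        if self.flags.use_st_attention:
            t = cfg.context_len
            self._add("sattn.P_s", np.ones((n, n)))
            self._add("sattn.Q_s", np.zeros((n, n)))
            self._add("sattn.Q1", rng.normal(0, 1.0 / np.sqrt(f_in), (f_in, 1)))
            self._add("sattn.Q2", rng.normal(0, 1.0 / np.sqrt(t), (1, t)))
            self._add("sattn.Q3", rng.normal(0, 1.0 / np.sqrt(f_in), (t, f_in)))
        if self.flags.use_rnn:
            d, hs = f_in, cfg.gru_hidden
            sw = np.sqrt(2.0 / (d + hs))
            su = np.sqrt(1.0 / hs)
            for gate in ("u", "d", "h"):
                self._add(f"gru.W_{gate}", rng.normal(0, sw, (d, hs)))
                self._add(f"gru.U_{gate}", rng.normal(0, su, (hs, hs)))
                self._add(f"gru.b_{gate}", np.zeros(hs))
            if self.flags.use_st_attention:
                t = cfg.context_len
                self._add("tattn.P_v", np.ones((t, t)))
                self._add("tattn.Q_v", np.zeros((t, t)))
                self._add("tattn.P1", rng.normal(0, 1.0 / np.sqrt(hs), (hs, 1)))
                self._add("tattn.P2", rng.normal(0, 1.0 / np.sqrt(n), (1, n)))
                self._add("tattn.P3", rng.normal(0, 1.0 / np.sqrt(hs), (n, hs)))
        d_fused = cfg.gat_hidden + (cfg.gru_hidden if self.flags.use_rnn else 0)
        s1 = np.sqrt(2.0 / (d_fused + N_STAGES))
        self._add("fc1.W", rng.normal(0, s1, (d_fused, N_STAGES)))
        self._add("fc1.b", np.zeros(N_STAGES))
        if self.flags.use_tse:
            s2 = np.sqrt(2.0 / (2 * N_STAGES))
            self._add("fc2.W", rng.normal(0, s2, (N_STAGES, N_STAGES)))
            self._add("fc2.b", np.zeros(N_STAGES))

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # -- forward -----------------------------------------------------------
    def _spatial_branch(self, x: np.ndarray) -> Tensor:
        """x: (B, T, n, F) -> pooled spatial features (B, gat_hidden)."""
        cfg = self.config
        center = cfg.context_len // 2
        h = Tensor(x[:, center])  # (B, n, F)
        for layer in range(cfg.gat_depth):
            acc: Tensor | None = None
            for head in range(cfg.n_heads):
                w = self.params[f"gat{layer}.h{head}.W"]
                a = self.params[f"gat{layer}.h{head}.a"]
                z = h @ w  # (B, n, Fh)
                fh = cfg.gat_hidden
                s_src = z @ a[:fh]  # (B, n, 1)
                s_dst = z @ a[fh:]  # (B, n, 1)
                scores = s_src + s_dst.swapaxes(-1, -2)  # (B, n, n)
                alpha = ad.masked_softmax(
                    ad.leaky_relu(scores, cfg.leaky_slope), self.mask, axis=-1
                )
                out = alpha @ z
                acc = out if acc is None else acc + out
            h_new = ad.sigmoid(acc * (1.0 / cfg.n_heads))
            if layer < cfg.gat_depth - 1:
                h = ad.relu(h_new @ self.params[f"inter{layer}.W"])
            else:
                h = h_new
        if self.flags.use_st_attention:
            a_s = self._spatial_attention_matrix(x)
            h = (h.swapaxes(-1, -2) @ a_s).swapaxes(-1, -2)  # re-mix node columns
        return h.mean(axis=1)  # pool over nodes

    def _spatial_attention_matrix(self, x: np.ndarray) -> Tensor:
        """Row-stochastic (B, n, n) spatial-domain attention from the raw
        feature block (time axis averaged)."""
        xbar = Tensor(x.mean(axis=1))  # (B, n, F)
        q1 = self.params["sattn.Q1"]
        q2 = self.params["sattn.Q2"]
        q3 = self.params["sattn.Q3"]
        left = (xbar @ q1) @ q2  # (B, n, T)
        right = q3 @ xbar.swapaxes(-1, -2)  # (B, T, n)
        raw = self.params["sattn.P_s"] * ad.sigmoid(
            left @ right + self.params["sattn.Q_s"]
        )
        return ad.softmax(raw, axis=-1)

    def _temporal_branch(self, x: np.ndarray) -> Tensor:
        """x: (B, T, n, F) -> pooled temporal features (B, gru_hidden)."""
        cfg = self.config
        xt = x.mean(axis=2)  # channel-aggregated inputs (B, T, F)
        batch = xt.shape[0]
        h = Tensor(np.zeros((batch, cfg.gru_hidden)))
        states = []
        p = self.params
        for t in range(cfg.context_len):
            x_t = Tensor(xt[:, t])
            u = ad.sigmoid(x_t @ p["gru.W_u"] + h @ p["gru.U_u"] + p["gru.b_u"])
            d = ad.sigmoid(x_t @ p["gru.W_d"] + h @ p["gru.U_d"] + p["gru.b_d"])
            hhat = ad.tanh(x_t @ p["gru.W_h"] + (d * h) @ p["gru.U_h"] + p["gru.b_h"])
            h = u * h + (1.0 - u) * hhat
            states.append(h)
        s = ad.stack(states, axis=1)  # (B, T, H)
        if self.flags.use_st_attention:
            a_t = self._temporal_attention_matrix(s)
            s = (s.swapaxes(-1, -2) @ a_t).swapaxes(-1, -2)
        return s.mean(axis=1)  # pool over time

    def _temporal_attention_matrix(self, s: Tensor) -> Tensor:
        p = self.params
        left = (s @ p["tattn.P1"]) @ p["tattn.P2"]  # (B, T, m)
        right = p["tattn.P3"] @ s.swapaxes(-1, -2)  # (B, m, T)
        raw = p["tattn.P_v"] * ad.sigmoid(left @ right + p["tattn.Q_v"])
        return ad.softmax(raw, axis=-1)

    def forward(self, x: np.ndarray) -> dict[str, Tensor]:
        """Forward a batch of context windows.

        Parameters
        ----------
        x
            Array of shape (B, context_len, n_channels, n_features).

        Returns
        -------
        dict with ``"probs"`` (the decision distribution: renormalized
        refined scores when the TSE is on, plain softmax otherwise),
        ``"stage_probs"`` (pre-refinement P), and with the TSE on also
        ``"attention"`` and ``"refined"``.
        """
        x = np.asarray(x, dtype=float)
        if x.ndim != 4 or x.shape[1] != self.config.context_len:
            raise ParameterError(
                f"expected (B, {self.config.context_len}, n, F) input, got {x.shape}"
            )
        pieces = [self._spatial_branch(x)]
        if self.flags.use_rnn:
            pieces.append(self._temporal_branch(x))
        fused = ad.concatenate(pieces, axis=-1) if len(pieces) > 1 else pieces[0]
        logits = fused @ self.params["fc1.W"] + self.params["fc1.b"]
        stage_probs = ad.softmax(logits, axis=-1)
        out = {"stage_probs": stage_probs}
        if self.flags.use_tse:
            attn = ad.sigmoid(stage_probs @ self.params["fc2.W"] + self.params["fc2.b"])
            refined = attn * stage_probs
            out["attention"] = attn
            out["refined"] = refined
            out["probs"] = refined / refined.sum(axis=-1, keepdims=True)
        else:
            out["probs"] = stage_probs
        return out

    def loss(
        self,
        x: np.ndarray,
        labels: np.ndarray,
        sample_weight: np.ndarray | None = None,
    ) -> Tensor:
        """Mean cross-entropy of the decision distribution.

        ``sample_weight`` (optional, one weight per sample) gives a
        weighted mean, normalized by the weight sum.
        """
        labels = np.asarray(labels, dtype=np.int64)
        probs = self.forward(x)["probs"]
        picked = probs[np.arange(labels.shape[0]), labels]
        nll = -ad.log(picked)
        if sample_weight is None:
            return nll.mean()
        w = np.asarray(sample_weight, dtype=float)
        return (nll * (w / w.sum())).sum()

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Decision probabilities for an array of windows, batched."""
        chunks = []
        for lo in range(0, x.shape[0], batch_size):
            chunks.append(self.forward(x[lo : lo + batch_size])["probs"].data)
        return np.concatenate(chunks, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Predicted stage indices (argmax, ties to the lower index)."""
        return np.argmax(self.predict_proba(x, batch_size), axis=1)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Save parameters and architecture to a flat ``.npz`` container."""
        meta = {
            "config": asdict(self.config),
            "flags": asdict(self.flags),
            "n_features": self.n_features,
        }
        arrays = {name: t.data for name, t in self.params.items()}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path, graph: ChannelGraph) -> "MganetModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            model = cls(
                graph=graph,
                n_features=meta["n_features"],
                config=ModelConfig(**meta["config"]),
                flags=AblationFlags(**meta["flags"]),
            )
            for name in model.params:
                model.params[name] = Tensor(data[name], requires_grad=True)
        return model
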