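"""E(3)-equivariant graph network for coordinate denoising.

The network stacks equivariant blocks; each block runs several graph
convolutional layers (GCLs) that update invariant node features from
messages

    m_ij = phi_e(h_i, h_j, ||x_i - x_j||^2, a_ij)
    m_i  = sum_j m_ij
    h_i' = h_i + phi_h(h_i, m_i)

followed by one equivariant coordinate update

    x_i' = x_i + C * sum_j (x_i - x_j) * phi_x(m_ij).

Feature updates see coordinates only through squared distances, so they
are invariant under rigid motion; the coordinate update moves points along
radial directions, so it is equivariant. The predicted noise is read out
as (final - input) coordinates, which is translation-invariant and
rotation-equivariant by construction.

Time conditioning appends a sinusoidal embedding of the diffusion timestep
to every node's input features. The implementation runs on the package's
own numpy autodiff core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .errors import ConfigError

# ---------------------------------------------------------------------------
# Low-level operations (numpy; used directly in tests and documentation)
# ---------------------------------------------------------------------------


def gcl_message(h_i: np.ndarray, h_j: np.ndarray, sqdist: np.ndarray,
                a_ij: np.ndarray, phi_e) -> np.ndarray:
    """m_ij = phi_e([h_i, h_j, ||x_i-x_j||^2, a_ij]) for each edge."""
    sqdist = np.asarray(sqdist, dtype=float).reshape(-1, 1)
    z = np.concatenate([np.atleast_2d(h_i), np.atleast_2d(h_j), sqdist,
                        np.atleast_2d(a_ij)], axis=1)
    return phi_e(z)


def coord_update(x: np.ndarray, edge_index: np.ndarray, weights: np.ndarray,
                 C: float | np.ndarray = 1.0) -> np.ndarray:
    """x_i' = x_i + C * sum_j (x_i - x_j) * w_ij.

    ``edge_index`` rows are (receiver i, sender j); ``weights`` holds the
    scalar phi_x(m_ij) per edge. ``C`` may be a scalar or per-node array.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if len(edge_index):
        rad = (x[edge_index[:, 0]] - x[edge_index[:, 1]]) * np.reshape(weights, (-1, 1))
        np.add.at(out, edge_index[:, 0], rad)
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return x + C * out


def node_update(h: np.ndarray, messages: np.ndarray, receiver: np.ndarray,
                phi_h, n_nodes: int | None = None) -> np.ndarray:
    """h_i' = phi_h(h_i, sum over incident messages)."""
    h = np.atleast_2d(h)
    n = n_nodes if n_nodes is not None else len(h)
    agg = np.zeros((n, messages.shape[1]))
    if len(receiver):
        np.add.at(agg, np.asarray(receiver, dtype=int), messages)
    return phi_h(h, agg)


def time_embedding(t: int, dim: int) -> np.ndarray:
    """Sinusoidal embedding of a diffusion timestep."""
    if dim % 2 != 0:
        raise ConfigError("time embedding width must be even")
    k = np.arange(dim // 2)
    angle = t / np.power(10000.0, 2 * k / dim)
    emb = np.empty(dim)
    emb[0::2] = np.sin(angle)
    emb[1::2] = np.cos(angle)
    return emb


# ---------------------------------------------------------------------------
# Trainable network
# ---------------------------------------------------------------------------


@dataclass
class EgnnConfig:
    n_blocks: int = 4             # equivariant blocks L
    hidden: int = 64              # feature width h
    gcls_per_block: int = 2
    feature_dim: int = 105        # input node-feature width (4 + 85 + pe_dim)
    edge_attr_dim: int = 4
    time_dim: int = 16
    # Aggregation constant of the coordinate update. "sqrt_degree"
    # (C = 1/sqrt(deg)) balances mobility and noise averaging: plain
    # degree normalisation caps selective movements far below the
    # distances a denoiser must cover, while an unnormalised sum is
    # unstable at realistic degrees (~100). Also available: "degree",
    # "constant".
    coord_agg: str = "sqrt_degree"
    coord_C: float = 1.0          # used when coord_agg == "constant"
    # Stability of the coordinate stream (standard EGNN practice): the
    # radial vector is normalised by (||x_i - x_j|| + 1) and the per-edge
    # weight is tanh-clamped to +-coords_range, bounding each block's
    # displacement; both operations preserve E(3) equivariance.
    coords_range: float = 3.0
    # Whether fragment atoms stay put inside the internal coordinate
    # stream, so later blocks measure distances against clean anchors
    # (the readout only ever matters for linker atoms either way).
    freeze_fragment: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.hidden < 1 or self.gcls_per_block < 1:
            raise ConfigError("n_blocks, hidden and gcls_per_block must be >= 1")
        if self.time_dim % 2 != 0:
            raise ConfigError("time_dim must be even")


def _linear_init(rng: np.random.Generator, fan_in: int, fan_out: int,
                 scale: float = 1.0) -> np.ndarray:
    return rng.normal(0.0, scale / np.sqrt(fan_in), size=(fan_in, fan_out))


class EquivariantDenoiser:
    """The trainable EGNN noise predictor epsilon_hat(x_t, t)."""

    def __init__(self, config: EgnnConfig, rng: np.random.Generator | int | None = None):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.config = config
        h = config.hidden
        # +1: linker-indicator channel, the conditioning flag telling the
        # denoiser which atoms are being regenerated
        in_dim = config.feature_dim + config.time_dim + 1
        e_in = 2 * h + 1 + config.edge_attr_dim
        p: dict[str, Tensor] = {}

        def lin(name: str, fi: int, fo: int, scale: float = 1.0) -> None:
            p[f"{name}.W"] = Tensor(_linear_init(rng, fi, fo, scale), requires_grad=True)
            p[f"{name}.b"] = Tensor(np.zeros(fo), requires_grad=True)

        lin("embed", in_dim, h)
        for l in range(config.n_blocks):
            for g in range(config.gcls_per_block):
                lin(f"b{l}.g{g}.e0", e_in, h)
                lin(f"b{l}.g{g}.e1", h, h)
                lin(f"b{l}.g{g}.h0", 2 * h, h)
                lin(f"b{l}.g{g}.h1", h, h)
            lin(f"b{l}.x0", h, h)
            # small final init keeps early coordinate updates gentle
            lin(f"b{l}.x1", h, 1, scale=1e-2)
        self.params = p

    # -- helpers -----------------------------------------------------------

    def _mlp2(self, name: str, z: Tensor, final_silu: bool) -> Tensor:
        p = self.params
        out = ad.silu(z @ p[f"{name}0.W"] + p[f"{name}0.b"])
        out = out @ p[f"{name}1.W"] + p[f"{name}1.b"]
        return ad.silu(out) if final_silu else out

    def forward(self, features: np.ndarray, coords: np.ndarray,
                edge_index: np.ndarray, edge_attr: np.ndarray, t: int,
                linker_mask: np.ndarray | None = None) -> Tensor:
        """Predicted per-atom noise as an autodiff tensor of shape (N, 3)."""
        cfg = self.config
        n = len(features)
        temb = np.broadcast_to(time_embedding(t, cfg.time_dim), (n, cfg.time_dim))
        flag = np.zeros((n, 1)) if linker_mask is None else \
            np.asarray(linker_mask, dtype=float).reshape(n, 1)
        feat = np.concatenate([features, temb, flag], axis=1)
        if feat.shape[1] != cfg.feature_dim + cfg.time_dim + 1:
            raise ConfigError(
                f"feature width {features.shape[1]} does not match config "
                f"feature_dim {cfg.feature_dim}")
        if edge_attr.shape[1] != cfg.edge_attr_dim:
            raise ConfigError("edge attribute width does not match config")

        p = self.params
        h = ad.silu(Tensor(feat) @ p["embed.W"] + p["embed.b"])
        x = Tensor(coords)
        x_in = x
        freeze = cfg.freeze_fragment and linker_mask is not None
        move = Tensor(flag) if freeze else Tensor(np.ones((n, 1)))

        recv = edge_index[:, 0] if len(edge_index) else np.zeros(0, dtype=int)
        send = edge_index[:, 1] if len(edge_index) else np.zeros(0, dtype=int)
        attr = Tensor(edge_attr)
        if cfg.coord_agg == "degree":
            deg = np.bincount(recv, minlength=n).astype(float) if len(recv) else np.zeros(n)
            C = (1.0 / np.maximum(deg, 1.0))[:, None]
        elif cfg.coord_agg == "sqrt_degree":
            deg = np.bincount(recv, minlength=n).astype(float) if len(recv) else np.zeros(n)
            C = (1.0 / np.sqrt(np.maximum(deg, 1.0)))[:, None]
        else:
            C = np.full((n, 1), cfg.coord_C)

        for l in range(cfg.n_blocks):
            diff = ad.gather(x, recv) - ad.gather(x, send)
            d2 = (diff * diff).sum_axis(1, keepdims=True)
            m = None
            for g in range(cfg.gcls_per_block):
                z = ad.concat([ad.gather(h, recv), ad.gather(h, send), d2, attr])
                m = self._mlp2(f"b{l}.g{g}.e", z, final_silu=True)
                agg = ad.segment_sum(m, recv, n)
                h = h + self._mlp2(f"b{l}.g{g}.h", ad.concat([h, agg]), final_silu=False)
            w = ad.tanh(self._mlp2(f"b{l}.x", m, final_silu=False)) * cfg.coords_range
            inv_norm = ad.power(ad.power(d2, 0.5) + 1.0, -1.0)
            # only atoms being regenerated move; conditioning atoms keep
            # their coordinates so later blocks see clean anchors
            x = x + move * (Tensor(C) * ad.segment_sum(diff * inv_norm * w, recv, n))
        return x - x_in

    def predict(self, features: np.ndarray, coords: np.ndarray,
                edge_index: np.ndarray, edge_attr: np.ndarray, t: int,
                linker_mask: np.ndarray | None = None) -> np.ndarray:
        """Forward pass on plain arrays (no autodiff graph; same math)."""
        from scipy.special import expit

        def _silu(a):
            return a * expit(a)

        cfg = self.config
        n = len(features)
        temb = np.broadcast_to(time_embedding(t, cfg.time_dim), (n, cfg.time_dim))
        flag = np.zeros((n, 1)) if linker_mask is None else \
            np.asarray(linker_mask, dtype=float).reshape(n, 1)
        feat = np.concatenate([features, temb, flag], axis=1)
        if feat.shape[1] != cfg.feature_dim + cfg.time_dim + 1:
            raise ConfigError(
                f"feature width {features.shape[1]} does not match config "
                f"feature_dim {cfg.feature_dim}")
        if edge_attr.shape[1] != cfg.edge_attr_dim:
            raise ConfigError("edge attribute width does not match config")
        p = {k: v.data for k, v in self.params.items()}
        h = _silu(feat @ p["embed.W"] + p["embed.b"])
        x = np.array(coords, dtype=np.float64)
        x_in = coords

        recv = edge_index[:, 0] if len(edge_index) else np.zeros(0, dtype=int)
        send = edge_index[:, 1] if len(edge_index) else np.zeros(0, dtype=int)
        if cfg.coord_agg == "degree":
            deg = np.bincount(recv, minlength=n).astype(float) if len(recv) else np.zeros(n)
            C = (1.0 / np.maximum(deg, 1.0))[:, None]
        elif cfg.coord_agg == "sqrt_degree":
            deg = np.bincount(recv, minlength=n).astype(float) if len(recv) else np.zeros(n)
            C = (1.0 / np.sqrt(np.maximum(deg, 1.0)))[:, None]
        else:
            C = np.full((n, 1), cfg.coord_C)

        def mlp2(name, z, final_silu):
            out = _silu(z @ p[f"{name}0.W"] + p[f"{name}0.b"])
            out = out @ p[f"{name}1.W"] + p[f"{name}1.b"]
            return _silu(out) if final_silu else out

        for l in range(cfg.n_blocks):
            diff = x[recv] - x[send]
            d2 = np.sum(diff * diff, axis=1, keepdims=True)
            m = None
            for g in range(cfg.gcls_per_block):
                z = np.concatenate([h[recv], h[send], d2, edge_attr], axis=1)
                m = mlp2(f"b{l}.g{g}.e", z, True)
                agg = ad.scatter_rows(np.zeros((n, m.shape[1])), recv, m)
                h = h + mlp2(f"b{l}.g{g}.h", np.concatenate([h, agg], axis=1), False)
            w = np.tanh(mlp2(f"b{l}.x", m, False)) * cfg.coords_range
            inv_norm = 1.0 / (np.sqrt(d2) + 1.0)
            move = flag if (cfg.freeze_fragment and linker_mask is not None) \
                else np.ones((n, 1))
            x = x + move * (C * ad.scatter_rows(np.zeros_like(x), recv, diff * inv_norm * w))
        return x - x_in

    # -- (de)serialisation -------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.array(arrays[k], dtype=np.float64)


@dataclass
class DenoiserState:
    """Trained denoiser + its noise schedule + training metadata.

    Serialises to a single ``.npz`` archive (parameters as arrays, config
    and metadata as embedded JSON) and reloads bit-stably.
    """

    denoiser: EquivariantDenoiser
    schedule: "object" = None  # NoiseSchedule; kept loose to avoid cycles
    meta: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        from .egnn_diffusion import NoiseSchedule  # local import, no cycle at load

        payload = {f"param/{k}": v for k, v in self.denoiser.state_arrays().items()}
        header = {
            "config": asdict(self.denoiser.config),
            "meta": self.meta,
            "schedule": None,
        }
        if self.schedule is not None:
            header["schedule"] = {"T": self.schedule.T}
            payload["schedule/betas"] = self.schedule.betas
        payload["header"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str) -> "DenoiserState":
        from .egnn_diffusion import NoiseSchedule

        with np.load(path) as z:
            header = json.loads(bytes(z["header"].tobytes()).decode())
            config = EgnnConfig(**header["config"])
            den = EquivariantDenoiser(config, rng=0)
            den.load_arrays({k[len("param/"):]: z[k] for k in z.files
                             if k.startswith("param/")})
            schedule = None
            if header["schedule"] is not None:
                schedule = NoiseSchedule.from_betas(z["schedule/betas"])
        return cls(den, schedule, header["meta"])


def denoise(graph, noisy_coords: np.ndarray, t: int, state: DenoiserState,
            linker_mask: np.ndarray | None = None) -> np.ndarray:
    """Predicted noise for every node of ``graph`` at timestep ``t``.

    The network's equivariant readout is a displacement field; under the
    x0 parameterization it is converted to the implied noise estimate
    using the state's schedule, under the eps parameterization it is the
    noise estimate itself. Either way the result transforms equivariantly
    under rigid motion of (graph coordinates, noisy coordinates).
    """
    if state.schedule is not None and not (1 <= t <= state.schedule.T):
        raise ValueError(f"timestep {t} outside schedule 1..{state.schedule.T}")
    delta = state.denoiser.predict(graph.node_features, noisy_coords,
                                   graph.edge_index, graph.edge_attr, t,
                                   linker_mask=linker_mask)
    if state.meta.get("parameterization", "x0") == "eps" or state.schedule is None:
        return delta
    from .egnn_diffusion import node_anchors

    ab = state.schedule.alpha_bar(t)
    y = noisy_coords - node_anchors(graph)
    y0_hat = y + delta
    return (y - np.sqrt(ab) * y0_hat) / np.sqrt(1.0 - ab)
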