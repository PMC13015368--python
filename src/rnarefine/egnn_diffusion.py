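"""Denoising diffusion over atomic coordinates with fragment conditioning.

A variance-preserving DDPM: forward noising

    x_t = sqrt(abar_t) * x_0 + sqrt(1 - abar_t) * eps,   eps ~ N(0, I)

and ancestral reverse steps

    x_{t-1} = (x_t - beta_t / sqrt(1 - abar_t) * eps_hat) / sqrt(alpha_t)
              + sqrt(beta_t) * z

driven by a polynomial noise schedule abar_t = clip((1 - (t/T)^p)^2).
Both processes touch *linker* atoms only; fragment atoms are pinned to
their input coordinates at every timestep during training and sampling,
which is what makes the generation conditional.

Diffusion runs in residue-local frames: each linker atom's coordinate is
expressed relative to the C4' atom of its own residue (which is pinned in
every mask mode) and divided by a fixed length scale, so the unit
Gaussian prior places atoms in a ~3 Å cloud around their own residue's
backbone anchor rather than in one global blob. This keeps the process
E(3)-equivariant — anchors and atoms transform together — while making
the reverse process a local geometry refinement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .egnn import DenoiserState, EgnnConfig, EquivariantDenoiser
from .errors import ConfigError, UndefinedLossError
from .graph_encoding import EncodingConfig, RnaGraph, encode_graph
from .masking import MaskAssignment, Phase1Params, SeveritySpec, hybrid_mask

logger = logging.getLogger(__name__)

#: Length scale (Å) mapping anchor-relative coordinates to diffusion units.
COORD_SCALE = 3.0


@dataclass
class NoiseSchedule:
    """beta/alpha/abar tables for timesteps t = 1..T (arrays of length T)."""

    betas: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if np.any(self.betas <= 0) or np.any(self.betas >= 1):
            raise ConfigError("betas must lie strictly in (0, 1)")
        self.alphas = 1.0 - self.betas
        self.alpha_bars = np.cumprod(self.alphas)

    @property
    def T(self) -> int:
        return len(self.betas)

    def beta(self, t: int) -> float:
        return float(self.betas[t - 1])

    def alpha(self, t: int) -> float:
        return float(self.alphas[t - 1])

    def alpha_bar(self, t: int) -> float:
        return float(self.alpha_bars[t - 1])

    @classmethod
    def from_betas(cls, betas: np.ndarray) -> "NoiseSchedule":
        return cls(np.asarray(betas, dtype=float))


def make_schedule(T: int = 100, exponent: float = 2.0,
                  clip: float = 1e-5) -> NoiseSchedule:
    """Polynomial schedule: abar_t = clip((1 - (t/T)^exponent)^2).

    Betas are derived as 1 - abar_t/abar_{t-1} (numerically clipped), and
    abar is recomputed as the running product of (1 - beta) so the two
    tables are self-consistent to machine precision.
    """
    if T < 2:
        raise ConfigError("schedule needs T >= 2")
    if exponent <= 0:
        raise ConfigError("schedule exponent must be positive")
    t = np.arange(1, T + 1, dtype=float)
    abar = np.clip((1.0 - (t / T) ** exponent) ** 2, clip, 1.0 - clip)
    abar = np.minimum.accumulate(abar)
    prev = np.concatenate([[1.0], abar[:-1]])
    betas = np.clip(1.0 - abar / prev, 1e-8, 0.9999)
    return NoiseSchedule(betas)


def forward_noise(x0: np.ndarray, t: int, eps: np.ndarray,
                  schedule: NoiseSchedule,
                  linker_mask: np.ndarray | None = None) -> np.ndarray:
    """x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps on linker atoms only."""
    ab = schedule.alpha_bar(t)
    xt = np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps
    if linker_mask is not None:
        out = np.array(x0, dtype=float, copy=True)
        out[linker_mask] = xt[linker_mask]
        return out
    return xt


def diffusion_loss(eps_true: np.ndarray, eps_hat: np.ndarray,
                   linker_mask: np.ndarray) -> float:
    """Mean over linker atoms of the squared noise residual norm."""
    if eps_true.shape != eps_hat.shape:
        raise ValueError("shape mismatch between true and predicted noise")
    linker_mask = np.asarray(linker_mask, dtype=bool)
    if not linker_mask.any():
        raise UndefinedLossError("loss undefined with an empty linker set")
    resid = eps_hat[linker_mask] - eps_true[linker_mask]
    return float(np.mean(np.sum(resid ** 2, axis=1)))


def reverse_step(xt: np.ndarray, t: int, eps_hat: np.ndarray,
                 schedule: NoiseSchedule,
                 rng: np.random.Generator | None = None,
                 linker_mask: np.ndarray | None = None,
                 z: np.ndarray | None = None) -> np.ndarray:
    """One ancestral DDPM step; noise z is zero at t = 1."""
    if t < 1:
        raise ValueError("reverse_step requires t >= 1")
    beta = schedule.beta(t)
    alpha = schedule.alpha(t)
    ab = schedule.alpha_bar(t)
    if z is None:
        if t > 1:
            if rng is None:
                raise ValueError("rng required for stochastic steps (t > 1)")
            z = rng.standard_normal(xt.shape)
        else:
            z = np.zeros_like(xt)
    mean = (xt - beta / np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(alpha)
    prev = mean + np.sqrt(beta) * z
    if linker_mask is not None:
        out = np.array(xt, dtype=float, copy=True)
        out[linker_mask] = prev[linker_mask]
        return out
    return prev


def node_anchors(graph: RnaGraph) -> np.ndarray:
    """Per-node anchor: the C4' coordinate of the node's residue (Å).

    C4' is part of the fragment in every mask mode, so anchors are fixed
    reference points throughout diffusion.
    """
    c4: dict[int, np.ndarray] = {}
    for k, (gi, name) in enumerate(graph.node_map):
        if name == "C4'":
            c4[gi] = graph.coords[k]
    try:
        return np.array([c4[gi] for gi, _ in graph.node_map])
    except KeyError as exc:
        raise ValueError(f"residue {exc} lacks a C4' anchor node") from exc


def constrained_sample(
    graph: RnaGraph,
    mask: MaskAssignment,
    state: DenoiserState,
    n_samples: int = 10,
    rng: np.random.Generator | None = None,
    scale: float = COORD_SCALE,
    x0_clamp: float | None = 3.0,
) -> np.ndarray:
    """Generate ``n_samples`` coordinate sets with fragment atoms pinned.

    Linker coordinates start from a standard normal (in diffusion units,
    centred on the fragment centroid) and are refined through T reverse
    steps; fragment atoms keep their input coordinates throughout and in
    the output. Each sample uses an independent substream of ``rng``.
    Returns an array of shape (n_samples, N, 3) in Å.
    """
    if state.schedule is None:
        raise ValueError("state carries no noise schedule; train first")
    rng = rng if rng is not None else np.random.default_rng()
    schedule = state.schedule
    linker = mask.linker_node_mask(graph)
    anchors = node_anchors(graph) / scale
    base = graph.coords / scale            # model units, absolute
    n_link = int(linker.sum())

    streams = rng.spawn(n_samples)
    out = np.empty((n_samples, len(base), 3))
    for k, sub in enumerate(streams):
        y = base - anchors                 # anchor-relative
        y[linker] = sub.standard_normal((n_link, 3))
        param = state.meta.get("parameterization", "x0")
        for t in range(schedule.T, 0, -1):
            x_abs = np.where(linker[:, None], anchors + y, base)
            delta = state.denoiser.predict(
                graph.node_features, x_abs, graph.edge_index, graph.edge_attr, t,
                linker_mask=linker)
            ab = schedule.alpha_bar(t)
            if param == "x0":
                y0_hat = y + delta
            else:
                y0_hat = (y - np.sqrt(1.0 - ab) * delta) / np.sqrt(ab)
            if x0_clamp is not None:
                # clamp the clean-coordinate estimate to the physically
                # plausible anchor neighbourhood; standard DDPM
                # stabilisation against compounding prediction error
                norm = np.linalg.norm(y0_hat, axis=1, keepdims=True)
                shrink = np.minimum(1.0, x0_clamp / np.maximum(norm, 1e-12))
                y0_hat = y0_hat * shrink
            eps_hat = (y - np.sqrt(ab) * y0_hat) / np.sqrt(1.0 - ab)
            y = reverse_step(y, t, eps_hat, schedule, sub, linker_mask=linker)
        final = np.array(graph.coords, dtype=float, copy=True)  # exact pinning
        final[linker] = (anchors + y)[linker] * scale
        out[k] = final
    return out


@dataclass
class TrainingExample:
    """One masked, noised training instance (kept mainly for inspection)."""

    graph: RnaGraph
    x0: np.ndarray
    mask: MaskAssignment
    t: int
    eps: np.ndarray


@dataclass
class TrainingConfig:
    n_steps: int = 1000
    lr: float = 1e-3
    lr_final: float | None = None   # cosine decay target; None = constant
    max_length: int = 200
    mode: str = "all_atom"
    scale: float = COORD_SCALE
    # Network parameterization: "x0" trains the equivariant stack to output
    # the clean anchor-relative coordinates (as a displacement from x_t);
    # the noise estimate used by the reverse process is derived from it.
    # "eps" trains the raw noise readout. Both are standard DDPM
    # parameterizations of the same model; x0 regresses directly onto the
    # target geometry and is far more sample-efficient at desk scale.
    parameterization: str = "x0"
    log_every: int = 100


def train(
    records: list[tuple],
    egnn_config: EgnnConfig,
    schedule: NoiseSchedule,
    rng: np.random.Generator | int | None = None,
    training: TrainingConfig | None = None,
    encoding: EncodingConfig | None = None,
    severity: SeveritySpec | None = None,
    phase1: Phase1Params | None = None,
) -> DenoiserState:
    """Train a denoiser on (structure, pairs) records with hybrid masks.

    Each step draws a record, a hybrid training mask, a timestep t uniform
    in 1..T and fresh Gaussian noise on the linker atoms, then takes one
    Adam step on the linker-restricted noise-matching loss. Structures
    longer than ``max_length`` residues are rejected at ingestion.
    """
    from ._autodiff import Adam, Tensor, gather

    if not records:
        raise ValueError("empty training set")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    training = training or TrainingConfig()
    encoding = encoding or EncodingConfig(
        resolution=training.mode,
        edge_scheme="contact_4type" if training.mode == "all_atom" else "relation_5type",
    )
    for s, _pairs in records:
        if s.n_residues > training.max_length:
            raise ValueError(
                f"structure {s.id} has {s.n_residues} residues; "
                f"maximum is {training.max_length}")

    graphs = [(encode_graph(s, pairs, encoding), s, pairs) for s, pairs in records]
    denoiser = EquivariantDenoiser(egnn_config, rng=rng.spawn(1)[0])
    opt = Adam(denoiser.params, lr=training.lr)
    history: list[float] = []

    for step in range(training.n_steps):
        if training.lr_final is not None:
            frac = step / max(1, training.n_steps - 1)
            opt.lr = training.lr_final + 0.5 * (training.lr - training.lr_final) \
                * (1 + np.cos(np.pi * frac))
        graph, s, pairs = graphs[int(rng.integers(len(graphs)))]
        mask = hybrid_mask(s, pairs, severity, phase1, mode=training.mode, rng=rng)
        linker = mask.linker_node_mask(graph)
        if not linker.any():
            continue
        anchors = node_anchors(graph) / training.scale
        u0 = graph.coords / training.scale
        y0 = u0 - anchors
        t = int(rng.integers(1, schedule.T + 1))
        eps = np.zeros_like(y0)
        eps[linker] = rng.standard_normal((int(linker.sum()), 3))
        yt = forward_noise(y0, t, eps, schedule, linker_mask=linker)
        xt = np.where(linker[:, None], anchors + yt, u0)

        delta = denoiser.forward(
            graph.node_features, xt, graph.edge_index, graph.edge_attr, t,
            linker_mask=linker)
        idx = np.nonzero(linker)[0]
        if training.parameterization == "x0":
            # y0_hat = y_t + delta; regression onto the clean geometry
            resid = gather(delta, idx) - Tensor(y0[idx] - yt[idx])
        else:
            resid = gather(delta, idx) - Tensor(eps[idx])
        loss_t = (resid * resid).sum() * (1.0 / len(idx))
        opt.zero_grad()
        loss_t.backward()
        opt.step()
        history.append(float(loss_t.data))
        if training.log_every and (step + 1) % training.log_every == 0:
            recent = float(np.mean(history[-training.log_every:]))
            logger.info("step %d  loss %.4f", step + 1, recent)

    meta = {"loss_history": history, "n_steps": training.n_steps,
            "mode": training.mode, "scale": training.scale,
            "parameterization": training.parameterization}
    return DenoiserState(denoiser, schedule, meta)


def split_dataset(
    records: list,
    rng: np.random.Generator | int | None = None,
    has_clashes=None,
) -> tuple[list, list, list]:
    """Deterministic shuffled 80/15/5 split.

    ``has_clashes(record) -> bool`` (default: a ``has_clashes`` attribute,
    else False) routes clash-containing records to the test partition;
    training and validation contain clash-free records only.
    """
    if len(records) < 20:
        raise ValueError("need at least 20 records to split")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if has_clashes is None:
        def has_clashes(rec):  # noqa: ANN001
            return bool(getattr(rec, "has_clashes", False))

    order = list(rng.permutation(len(records)))
    n = len(records)
    n_train = int(round(0.80 * n))
    n_val = int(round(0.15 * n))

    clashed = [k for k in order if has_clashes(records[k])]
    clean = [k for k in order if not has_clashes(records[k])]

    train_idx = clean[:n_train]
    val_idx = clean[n_train:n_train + n_val]
    test_idx = clean[n_train + n_val:] + clashed
    if len(train_idx) < n_train or len(val_idx) < n_val:
        logger.warning("too many clash-containing records; "
                       "train/validation partitions are short")
    return ([records[k] for k in train_idx],
            [records[k] for k in val_idx],
            [records[k] for k in test_idx])
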