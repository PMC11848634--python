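"""The contact-map transformer: expression vector in, upper triangle out.

A cell's gene-expression vector is reshaped to an (8m, 8n) matrix, cut into
an 8 x 8 grid of 64 patches, linearly embedded with learned position
embeddings, and encoded by a pre-norm multi-head-attention transformer.
A per-token head maps each of the 64 token features to a latent vector
(default width 1000); a fully connected layer projects the latent tokens
to a second, narrower transformer (the decoder), whose flattened output a
final fully connected layer turns into the N_c = K_h(K_h-1)/2
upper-triangle contact values.
A softplus keeps predicted contacts non-negative (``linear_head`` disables
it).

Training minimizes a modified focal loss: with per-sample squared-error sum
L_i over interactions, the batch loss is mean_i (1 - exp(-L_i))^gamma * L_i,
which down-weights samples the model already fits well while preserving the
MSE optimum (gamma = 0 recovers plain MSE).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from contactseer.autodiff import Adam, Tensor, layer_norm, parameters, softmax
from contactseer.io_formats import ContactStack, ExpressionMatrix, GenomicFeature

N_PATCHES = 64  # fixed 8 x 8 patch grid


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``scale`` shrinks every width hyperparameter proportionally (rounded to
    a multiple of the head count) for desk-scale runs; depth and head count
    are untouched.
    """

    encoder_dim: int = 1024
    encoder_depth: int = 6
    encoder_heads: int = 8
    encoder_mlp_dim: int = 2048
    latent_dim: int = 1000
    decoder_dim: int = 512
    decoder_depth: int = 6
    decoder_heads: int = 8
    decoder_mlp_dim: int = 2048
    gamma: float = 2.0
    lr: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    batch_size: int = 8
    seed: int = 0
    scale: float = 1.0
    linear_head: bool = False
    include_diagonal: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.scale <= 1):
            raise ValueError("scale must lie in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    def scaled(self) -> "ModelConfig":
        """Config with width hyperparameters multiplied by ``scale``."""
        if self.scale == 1.0:
            return self

        def rnd(x: int, mult: int) -> int:
            return max(mult, int(round(x * self.scale / mult)) * mult)

        cfg = ModelConfig(**{**asdict(self), "scale": 1.0})
        cfg.encoder_dim = rnd(self.encoder_dim, self.encoder_heads)
        cfg.encoder_mlp_dim = rnd(self.encoder_mlp_dim, self.encoder_heads)
        cfg.latent_dim = rnd(self.latent_dim, self.encoder_heads)
        cfg.decoder_dim = rnd(self.decoder_dim, self.decoder_heads)
        cfg.decoder_mlp_dim = rnd(self.decoder_mlp_dim, self.decoder_heads)
        return cfg


@dataclass
class ReshapeSpec:
    """How a K_R-gene vector becomes an (8m, 8n) matrix of 64 patches.

    K_used is K_R truncated down to a multiple of 64; the dropped genes are
    those of lowest total count (ties by index).  (m, n) is the factor pair
    of K_used/64 with minimal |m - n| and m <= n.
    """

    K_R: int
    K_used: int
    m: int
    n: int
    dropped_gene_indices: list[int] = field(default_factory=list)

    @property
    def kept_gene_indices(self) -> np.ndarray:
        dropped = set(self.dropped_gene_indices)
        return np.array([i for i in range(self.K_R) if i not in dropped])

    @property
    def input_shape(self) -> tuple[int, int]:
        return (8 * self.m, 8 * self.n)


def make_reshape_spec(K_R: int, gene_totals: np.ndarray | None = None) -> ReshapeSpec:
    if K_R < 64:
        raise ValueError(f"need at least 64 genes to form 64 patches, got {K_R}")
    K_used = (K_R // 64) * 64
    p = K_used // 64
    best = (1, p)
    for m in range(1, int(np.sqrt(p)) + 1):
        if p % m == 0:
            best = (m, p // m)  # grows toward the most balanced pair
    m, n = best
    n_drop = K_R - K_used
    if n_drop > 0:
        if gene_totals is None:
            gene_totals = np.zeros(K_R)
        # lowest-total genes dropped; stable sort breaks ties by index
        dropped = list(np.argsort(gene_totals, kind="stable")[:n_drop])
        dropped = [int(i) for i in dropped]
    else:
        dropped = []
    return ReshapeSpec(K_R=K_R, K_used=K_used, m=m, n=n, dropped_gene_indices=dropped)


def patchify(matrix: np.ndarray, m: int, n: int) -> np.ndarray:
    """(8m, 8n) matrix -> (64, m*n) patches in row-major grid order."""
    matrix = np.asarray(matrix)
    if matrix.shape != (8 * m, 8 * n):
        raise ValueError(f"expected shape {(8 * m, 8 * n)}, got {matrix.shape}")
    patches = matrix.reshape(8, m, 8, n).transpose(0, 2, 1, 3).reshape(64, m * n)
    return patches


def unpatchify(patches: np.ndarray, m: int, n: int) -> np.ndarray:
    patches = np.asarray(patches)
    if patches.shape != (64, m * n):
        raise ValueError(f"expected shape {(64, m * n)}, got {patches.shape}")
    return patches.reshape(8, 8, m, n).transpose(0, 2, 1, 3).reshape(8 * m, 8 * n)


# ---------------------------------------------------------------------------
# upper-triangle codec


def extract_uppertri(c: np.ndarray, include_diagonal: bool = False) -> np.ndarray:
    """Row-major upper-triangle flattening of a square matrix."""
    c = np.asarray(c)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {c.shape}")
    iu = np.triu_indices(c.shape[0], k=0 if include_diagonal else 1)
    return c[iu]


def reconstruct_symmetric(vec: np.ndarray, K_h: int,
                          include_diagonal: bool = False) -> np.ndarray:
    vec = np.asarray(vec)
    out = np.zeros((K_h, K_h))
    iu = np.triu_indices(K_h, k=0 if include_diagonal else 1)
    if vec.shape != iu[0].shape:
        raise ValueError(f"vector length {vec.size} does not match K_h={K_h}")
    out[iu] = vec
    out = out + np.triu(out, k=1).T
    return out


def n_interactions(K_h: int, include_diagonal: bool = False) -> int:
    return K_h * (K_h + 1) // 2 if include_diagonal else K_h * (K_h - 1) // 2


# ---------------------------------------------------------------------------
# loss


def focal_loss(pred: Tensor | np.ndarray, target: np.ndarray, gamma: float) -> Tensor:
    """Mean over the batch of (1 - e^(-L_i))^gamma * L_i.

    L_i is the squared-error sum over a sample's interactions (no 1/N_c).
    """
    pred = Tensor._lift(pred)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    diff = pred - Tensor(target)
    per_sample = (diff ** 2.0).sum(axis=1)  # L_i
    focal = (1.0 - (-per_sample).exp()) ** gamma if gamma != 0 else 1.0
    return (per_sample * focal).mean()


# ---------------------------------------------------------------------------
# network


def _init(rng: np.random.Generator, *shape, std: float | None = None) -> Tensor:
    """Fan-in-scaled (LeCun) normal init; pass ``std`` to override."""
    if std is None:
        fan_in = shape[0] if len(shape) == 2 else shape[-1]
        std = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class _SelfAttentionBlock:
    """Pre-norm transformer block with separate Q/K/V projections."""

    def __init__(self, rng, dim: int, heads: int, mlp_dim: int):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads = dim, heads
        self.dh = dim // heads
        self.ln1_g = Tensor(np.ones(dim), requires_grad=True)
        self.ln1_b = Tensor(np.zeros(dim), requires_grad=True)
        self.w_q = _init(rng, dim, dim)
        self.w_k = _init(rng, dim, dim)
        self.w_v = _init(rng, dim, dim)
        self.b_q = Tensor(np.zeros(dim), requires_grad=True)
        self.b_k = Tensor(np.zeros(dim), requires_grad=True)
        self.b_v = Tensor(np.zeros(dim), requires_grad=True)
        self.w_o = _init(rng, dim, dim)
        self.b_o = Tensor(np.zeros(dim), requires_grad=True)
        self.ln2_g = Tensor(np.ones(dim), requires_grad=True)
        self.ln2_b = Tensor(np.zeros(dim), requires_grad=True)
        self.w1 = _init(rng, dim, mlp_dim)
        self.b1 = Tensor(np.zeros(mlp_dim), requires_grad=True)
        self.w2 = _init(rng, mlp_dim, dim)
        self.b2 = Tensor(np.zeros(dim), requires_grad=True)

    def _heads(self, t: Tensor, b: int, s: int) -> Tensor:
        return t.reshape(b, s, self.heads, self.dh).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        b, s, _ = x.shape
        h = layer_norm(x, self.ln1_g, self.ln1_b)
        q = self._heads(h @ self.w_q + self.b_q, b, s)
        k = self._heads(h @ self.w_k + self.b_k, b, s)
        v = self._heads(h @ self.w_v + self.b_v, b, s)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, s, self.dim)
        x = x + (out @ self.w_o + self.b_o)
        h2 = layer_norm(x, self.ln2_g, self.ln2_b)
        x = x + ((h2 @ self.w1 + self.b1).gelu() @ self.w2 + self.b2)
        return x


class ContactTransformer:
    """Encoder-decoder network mapping an expression vector to contacts."""

    def __init__(self, config: ModelConfig, reshape_spec: ReshapeSpec, K_h: int,
                 gene_names: list[str] | None = None,
                 region: GenomicFeature | None = None):
        self.base_config = config
        cfg = config.scaled()
        self.config = cfg
        self.spec = reshape_spec
        self.K_h = K_h
        self.gene_names = gene_names
        self.region = region
        self.n_out = n_interactions(K_h, config.include_diagonal)
        rng = np.random.default_rng(config.seed)
        patch_dim = reshape_spec.m * reshape_spec.n
        d = cfg.encoder_dim
        self.patch_w = _init(rng, patch_dim, d)
        self.patch_b = Tensor(np.zeros(d), requires_grad=True)
        self.pos_emb = _init(rng, N_PATCHES, d, std=0.02)
        self.enc_blocks = [
            _SelfAttentionBlock(rng, d, cfg.encoder_heads, cfg.encoder_mlp_dim)
            for _ in range(cfg.encoder_depth)
        ]
        self.enc_ln_g = Tensor(np.ones(d), requires_grad=True)
        self.enc_ln_b = Tensor(np.zeros(d), requires_grad=True)
        # per-token latent head ("set of latent vectors"), then per-token
        # projection down to the decoder width
        self.latent_w = _init(rng, d, cfg.latent_dim)
        self.latent_b = Tensor(np.zeros(cfg.latent_dim), requires_grad=True)
        dd = cfg.decoder_dim
        self.dec_in_w = _init(rng, cfg.latent_dim, dd)
        self.dec_in_b = Tensor(np.zeros(dd), requires_grad=True)
        self.dec_pos_emb = _init(rng, N_PATCHES, dd, std=0.02)
        self.dec_blocks = [
            _SelfAttentionBlock(rng, dd, cfg.decoder_heads, cfg.decoder_mlp_dim)
            for _ in range(cfg.decoder_depth)
        ]
        self.dec_ln_g = Tensor(np.ones(dd), requires_grad=True)
        self.dec_ln_b = Tensor(np.zeros(dd), requires_grad=True)
        self.head_w = _init(rng, N_PATCHES * dd, self.n_out)
        self.head_b = Tensor(np.zeros(self.n_out), requires_grad=True)
        # per-gene input standardization (log1p scale), fit during training;
        # applied inside the forward graph so attributions chain through it
        self.input_stats: dict[str, np.ndarray] | None = None

    def fit_input_stats(self, inputs: np.ndarray) -> None:
        """Fit log1p-scale per-gene mean/sd on training inputs (kept genes)."""
        logged = np.log1p(np.asarray(inputs, dtype=float))
        mu = logged.mean(axis=0)
        sd = logged.std(axis=0)
        self.input_stats = {"mu": mu, "sd": np.where(sd > 0, sd, 1.0)}

    # -- forward -----------------------------------------------------------

    def prepare_input(self, g: np.ndarray) -> np.ndarray:
        """Truncate to kept genes; accepts a single vector or a batch."""
        g = np.asarray(g, dtype=float)
        single = g.ndim == 1
        if single:
            g = g[None, :]
        if g.shape[1] != self.spec.K_R:
            raise ValueError(
                f"input has {g.shape[1]} genes; model expects {self.spec.K_R}"
            )
        g = g[:, self.spec.kept_gene_indices]
        return g[0] if single else g

    def forward(self, g: Tensor | np.ndarray) -> Tensor:
        """Batched forward pass; input (B, K_used) -> output (B, N_c)."""
        x = Tensor._lift(g)
        if x.ndim == 1:
            x = x.reshape(1, -1)
        b = x.shape[0]
        if x.shape[1] != self.spec.K_used:
            raise ValueError(
                f"expected {self.spec.K_used} input values, got {x.shape[1]}"
            )
        if self.input_stats is not None:
            x = ((x + 1.0).log() - self.input_stats["mu"]) \
                * (1.0 / self.input_stats["sd"])
        m, n = self.spec.m, self.spec.n
        # reshape to (8m, 8n) then cut the 8x8 patch grid, per sample
        x = x.reshape(b, 8, m, 8, n).transpose(0, 1, 3, 2, 4).reshape(
            b, N_PATCHES, m * n)
        h = x @ self.patch_w + self.patch_b + self.pos_emb
        for blk in self.enc_blocks:
            h = blk(h)
        h = layer_norm(h, self.enc_ln_g, self.enc_ln_b)
        latent = h @ self.latent_w + self.latent_b  # (b, 64, latent_dim)
        dd = self.config.decoder_dim
        dec = latent @ self.dec_in_w + self.dec_in_b  # (b, 64, dd)
        dec = dec + self.dec_pos_emb
        for blk in self.dec_blocks:
            dec = blk(dec)
        dec = layer_norm(dec, self.dec_ln_g, self.dec_ln_b)
        out = dec.reshape(b, N_PATCHES * dd) @ self.head_w + self.head_b
        if not self.config.linear_head:
            out = out.softplus()
        return out

    def parameters(self) -> list[Tensor]:
        return parameters(
            [self.patch_w, self.patch_b, self.pos_emb, self.enc_blocks,
             self.enc_ln_g, self.enc_ln_b, self.latent_w, self.latent_b,
             self.dec_in_w, self.dec_in_b, self.dec_pos_emb, self.dec_blocks,
             self.dec_ln_g, self.dec_ln_b, self.head_w, self.head_b]
        )

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "config": asdict(self.base_config),
            "spec": asdict(self.spec),
            "K_h": self.K_h,
            "gene_names": self.gene_names,
            "region": None if self.region is None else
                      [self.region.name, self.region.chrom,
                       self.region.start, self.region.end],
        }
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        if self.input_stats is not None:
            arrays["input_mu"] = self.input_stats["mu"]
            arrays["input_sd"] = self.input_stats["sd"]
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "ContactTransformer":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            cfg = ModelConfig(**meta["config"])
            spec = ReshapeSpec(**meta["spec"])
            region = None
            if meta["region"] is not None:
                name, chrom, start, end = meta["region"]
                region = GenomicFeature(name, chrom, int(start), int(end))
            model = cls(cfg, spec, int(meta["K_h"]),
                        gene_names=meta["gene_names"], region=region)
            for i, p in enumerate(model.parameters()):
                p.data = z[f"p{i}"]
            if "input_mu" in z:
                model.input_stats = {"mu": z["input_mu"], "sd": z["input_sd"]}
        return model


# ---------------------------------------------------------------------------
# training and prediction


def train(
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: ModelConfig,
    epochs: int = 30,
    gene_names: list[str] | None = None,
    region: GenomicFeature | None = None,
    model: ContactTransformer | None = None,
) -> tuple[ContactTransformer, list[float]]:
    """Train on (expression vector, local contact map) pairs.

    Returns the model and the loss history: entry 0 is the untrained
    model's mean focal loss, entry k the mean over epoch k's batches.
    All randomness (init, batch shuffling) flows from ``config.seed``.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    K_R = dataset[0][0].size
    K_h = dataset[0][1].shape[0]
    for g, c in dataset:
        if g.size != K_R or c.shape != (K_h, K_h):
            raise ValueError("inconsistent shapes in dataset")
    gene_totals = np.sum([g for g, _ in dataset], axis=0)
    spec = make_reshape_spec(K_R, gene_totals)
    if model is None:
        model = ContactTransformer(config, spec, K_h, gene_names=gene_names,
                                   region=region)
    inputs = np.stack([model.prepare_input(g) for g, _ in dataset])
    fresh = model.input_stats is None
    if fresh:
        model.fit_input_stats(inputs)
    targets = np.stack([
        extract_uppertri(c, config.include_diagonal) for _, c in dataset
    ])
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.lr,
               betas=(config.adam_beta1, config.adam_beta2))
    n = len(dataset)
    bs = max(1, config.batch_size)
    # history[0] is the untrained model's loss; history[k] the epoch-k mean
    init_losses = [
        float(focal_loss(model.forward(Tensor(inputs[s:s + bs])),
                         targets[s:s + bs], config.gamma).data)
        for s in range(0, n, bs)
    ]
    history: list[float] = [float(np.mean(init_losses))]
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            x = Tensor(inputs[idx])
            pred = model.forward(x)
            loss = focal_loss(pred, targets[idx], config.gamma)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
    return model, history


def predict(model: ContactTransformer, expr: ExpressionMatrix | np.ndarray,
            batch_size: int = 32) -> ContactStack:
    """Predict one symmetric K_h x K_h local map per cell (diagonal zero)."""
    import scipy.sparse as sp

    if isinstance(expr, ExpressionMatrix):
        if model.gene_names is not None and expr.gene_names != model.gene_names:
            missing = sorted(set(model.gene_names) - set(expr.gene_names))
            raise ValueError(
                f"gene set mismatch with the trained model; missing: {missing[:10]}"
            )
        counts = expr.counts
        cell_ids = list(expr.cell_ids)
        labels = list(expr.cell_labels)
    else:
        counts = np.asarray(expr, dtype=float)
        cell_ids = [f"cell{i}" for i in range(counts.shape[0])]
        labels = ["unknown"] * counts.shape[0]
    x = model.prepare_input(counts)
    maps = []
    for start in range(0, x.shape[0], batch_size):
        out = model.forward(x[start:start + batch_size]).data
        for row in out:
            maps.append(sp.csr_matrix(reconstruct_symmetric(
                row, model.K_h, model.config.include_diagonal)))
    if model.region is not None:
        binsize = max(1, model.region.length // model.K_h)
        bins = [
            GenomicFeature(f"bin{i}", model.region.chrom,
                           model.region.start + i * binsize,
                           model.region.start + (i + 1) * binsize)
            for i in range(model.K_h)
        ]
    else:
        binsize = 10_000
        bins = [GenomicFeature(f"bin{i}", "chr0", i * binsize, (i + 1) * binsize)
                for i in range(model.K_h)]
    return ContactStack(binsize, bins, maps, cell_ids, labels)
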