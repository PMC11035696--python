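"""Graph-to-sequence generative model.

A graph transformer encoder embeds a ligand 2D graph or a pocket 3D graph,
runs L = 3 message-passing layers (messages conditioned on Fourier distance
features in 3D), concatenates the per-layer node states, projects them to
final atomic features, pools them with attention over learnable seed vectors
(permutation invariant), and emits two latent vectors l1 and l2.  These
initialise the hidden states of a two-layer LSTM decoder that generates the
output molecule token by token.  An optional "wishlist" of six
physicochemical properties (z-scored by training-set statistics) is
concatenated to the pooled representation before the latent MLPs, steering
generation toward the requested property profile.

Sampling uses a temperature-scaled softmax over the decoder logits:
P(token) = exp(logit/T) / sum exp(logit/T).  Low T sharpens toward the
argmax; high T approaches uniform.  T = 0.5 is the default operating point.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .alphabet import TokenAlphabet, detokenize, tokenize
from .autodiff import Tensor, concat, gather_rows, segment_sum, softmax_cross_entropy
from .chem import canonical_smiles
from .nn import LSTMCell, MLP, Adam, Embedding, Linear, Module

__all__ = [
    "GeneratorConfig",
    "GeneratorModel",
    "PropertyWishlist",
    "SampledString",
    "count_parameters",
    "greedy_decode",
    "load_model",
    "sample",
    "sample_batch",
    "save_model",
    "temperature_probs",
    "train_generator",
]

PROPERTY_NAMES = ("mw", "rot_bonds", "hba", "hbd", "psa", "logp")


@dataclass(frozen=True)
class PropertyWishlist:
    """Desired property profile for a generated molecule.

    Units: mw in g/mol, psa in A^2, rot_bonds/hba/hbd are counts, logp is
    dimensionless.
    """

    mw: float
    rot_bonds: float
    hba: float
    hbd: float
    psa: float
    logp: float

    def as_array(self) -> np.ndarray:
        arr = np.array([self.mw, self.rot_bonds, self.hba, self.hbd, self.psa, self.logp], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("all six properties must be finite")
        if min(self.rot_bonds, self.hba, self.hbd) < 0:
            raise ValueError("counts must be >= 0")
        return arr


@dataclass
class GeneratorConfig:
    mode: str = "ligand"          # "ligand" (2D input) or "structure" (3D input)
    node_dim: int = 128           # per-feature embedding width
    hidden_dim: int = 256         # message-passing width
    latent_dim: int = 256         # latent vectors == LSTM hidden size
    token_emb_dim: int = 64
    n_layers: int = 3
    n_freq: int = 8               # Fourier frequencies for 3D edges
    n_seeds: int = 4              # attention-pooling seed vectors
    pooling: str = "attention"    # or "sum"
    conditioned: bool = False
    max_len: int = 100            # token cap per generated string


class GeneratorModel(Module):
    """Encoder + decoder parameters; construct with a config and alphabet."""

    def __init__(
        self,
        config: GeneratorConfig,
        alphabet: TokenAlphabet,
        seed: int = 0,
        prop_mean: np.ndarray | None = None,
        prop_std: np.ndarray | None = None,
    ):
        rng = np.random.default_rng(seed)
        self.config = config
        self.alphabet = alphabet
        self.seed = seed
        self.prop_mean = np.zeros(6) if prop_mean is None else np.asarray(prop_mean, float)
        self.prop_std = np.ones(6) if prop_std is None else np.asarray(prop_std, float)
        c = config

        # ----- encoder -----
        if c.mode == "ligand":
            self.emb_atom = Embedding(10, c.node_dim, rng)
            self.emb_ring = Embedding(2, c.node_dim, rng)
            self.emb_arom = Embedding(2, c.node_dim, rng)
            self.emb_hyb = Embedding(4, c.node_dim, rng)
            in_dim = 4 * c.node_dim
        elif c.mode == "structure":
            self.emb_elem = Embedding(22, c.node_dim, rng)
            self.emb_aa = Embedding(225, c.node_dim, rng)
            in_dim = 2 * c.node_dim + 2  # + dist_to_ligand, b_factor
        else:
            raise ValueError("mode must be 'ligand' or 'structure'")
        self.node_mlp = MLP(in_dim, c.hidden_dim, c.hidden_dim, rng)

        edge_extra = 2 * c.n_freq if c.mode == "structure" else 0
        self.psi = [MLP(2 * c.hidden_dim + edge_extra, c.hidden_dim, c.hidden_dim, rng) for _ in range(c.n_layers)]
        self.phi = [MLP(2 * c.hidden_dim, c.hidden_dim, c.hidden_dim, rng) for _ in range(c.n_layers)]
        self.proj = MLP(c.n_layers * c.hidden_dim, c.hidden_dim, c.hidden_dim, rng)
        self.pool_seeds = Tensor(rng.normal(0, 0.1, size=(c.n_seeds, c.hidden_dim)), requires_grad=True)
        pooled_dim = c.n_seeds * c.hidden_dim if c.pooling == "attention" else c.hidden_dim
        lat_in = pooled_dim + (6 if c.conditioned else 0)
        self.lat1 = MLP(lat_in, c.hidden_dim, c.latent_dim, rng)
        self.lat2 = MLP(lat_in, c.hidden_dim, c.latent_dim, rng)

        # ----- decoder -----
        self.tok_emb = Embedding(alphabet.size, c.token_emb_dim, rng)
        self.lstm1 = LSTMCell(c.token_emb_dim, c.latent_dim, rng)
        self.lstm2 = LSTMCell(c.latent_dim, c.latent_dim, rng)
        self.out = Linear(c.latent_dim, alphabet.size, rng)

    # -- submodule grouping for parameter accounting -------------------------
    def encoder_modules(self) -> list[Module]:
        mods = [self.node_mlp, *self.psi, *self.phi, self.proj, self.lat1, self.lat2]
        if self.config.mode == "ligand":
            mods = [self.emb_atom, self.emb_ring, self.emb_arom, self.emb_hyb] + mods
        else:
            mods = [self.emb_elem, self.emb_aa] + mods
        return mods

    def decoder_modules(self) -> list[Module]:
        return [self.tok_emb, self.lstm1, self.lstm2, self.out]

    # -- property standardization --------------------------------------------
    def standardize_properties(self, props: np.ndarray) -> np.ndarray:
        return (np.asarray(props, float) - self.prop_mean) / self.prop_std

    def destandardize_properties(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, float) * self.prop_std + self.prop_mean

    # -- encoder --------------------------------------------------------------
    def encode(self, graphs, wishlists=None) -> tuple[Tensor, Tensor]:
        """Latent vectors (l1, l2) for one graph or a list of graphs.

        In conditioned mode `wishlists` (one per graph, PropertyWishlist or
        6-vector) is mandatory; in unconditioned mode it must be omitted.
        """
        single = not isinstance(graphs, (list, tuple))
        if single:
            graphs = [graphs]
        if self.config.conditioned and wishlists is None:
            raise ValueError("conditioned model requires wishlists (all six properties)")
        batch = _batch_graphs(graphs, self.config.mode)
        return self._encode_batch(batch, _wishlist_matrix(wishlists, len(graphs), self))

    def _encode_batch(self, batch: dict, props_z: np.ndarray | None) -> tuple[Tensor, Tensor]:
        c = self.config
        if batch["n_nodes"] == 0:
            raise ValueError("cannot encode an empty graph")
        if c.mode == "ligand":
            feats = concat(
                [
                    self.emb_atom(batch["atom_type"]),
                    self.emb_ring(batch["ring"]),
                    self.emb_arom(batch["arom"]),
                    self.emb_hyb(batch["hyb"]),
                ],
                axis=1,
            )
        else:
            scalars = Tensor(np.stack([batch["dist"], batch["b_factor"]], axis=1))
            feats = concat(
                [self.emb_elem(batch["elem"]), self.emb_aa(batch["aa"]), scalars], axis=1
            )
        h = self.node_mlp(feats).tanh()
        recv, send = batch["recv"], batch["send"]
        n_nodes = batch["n_nodes"]
        fourier = Tensor(batch["fourier"]) if c.mode == "structure" else None

        layer_states = []
        for l in range(c.n_layers):
            parts = [gather_rows(h, recv), gather_rows(h, send)]
            if fourier is not None:
                parts.append(fourier)
            messages = self.psi[l](concat(parts, axis=1)).tanh()
            agg = segment_sum(messages, recv, n_nodes)
            h = self.phi[l](concat([h, agg], axis=1)).tanh()
            layer_states.append(h)

        H = self.proj(concat(layer_states, axis=1)).tanh()
        seg = batch["graph_ids"]
        n_graphs = batch["n_graphs"]
        if c.pooling == "attention":
            scores = (H @ _transpose(self.pool_seeds)) * (1.0 / np.sqrt(c.hidden_dim))
            alpha = _segment_softmax(scores, seg, n_graphs)
            pooled_parts = []
            for k in range(c.n_seeds):
                weighted = alpha[:, k : k + 1] * H
                pooled_parts.append(segment_sum(weighted, seg, n_graphs))
            pooled = concat(pooled_parts, axis=1)
        else:
            pooled = segment_sum(H, seg, n_graphs)

        if self.config.conditioned:
            pooled = concat([pooled, Tensor(props_z)], axis=1)
        return self.lat1(pooled).tanh(), self.lat2(pooled).tanh()

    # -- decoder --------------------------------------------------------------
    def teacher_forced_loss(self, l1: Tensor, l2: Tensor, tokens: np.ndarray) -> Tensor:
        """Mean per-token cross-entropy with pad positions masked."""
        pad = self.alphabet.pad_idx
        inputs, targets = tokens[:, :-1], tokens[:, 1:]
        mask = (targets != pad).astype(float)
        n_tokens = mask.sum()
        B = tokens.shape[0]
        zeros = Tensor(np.zeros((B, self.config.latent_dim)))
        c1 = c2 = zeros
        h1, h2 = l1, l2
        total = None
        for t in range(inputs.shape[1]):
            if mask[:, t].sum() == 0:
                break
            k = self.tok_emb(inputs[:, t])
            h1, c1 = self.lstm1(k, h1, c1)
            h2, c2 = self.lstm2(h1, h2, c2)
            logits = self.out(h2)
            step = softmax_cross_entropy(logits, targets[:, t], mask[:, t])
            total = step if total is None else total + step
        return total * (1.0 / n_tokens)

    def decode_step(
        self,
        l1: np.ndarray,
        l2: np.ndarray,
        c1: np.ndarray,
        c2: np.ndarray,
        prev_token: np.ndarray,
    ):
        """One decoder step (numpy fast path): returns new states and logits."""
        prev_token = np.atleast_1d(np.asarray(prev_token, dtype=np.intp))
        if np.any(prev_token >= self.alphabet.size):
            raise ValueError("prev_token outside alphabet")
        k = self.tok_emb.table.data[prev_token]
        l1n, c1n = self.lstm1.step_numpy(k, l1, c1)
        l2n, c2n = self.lstm2.step_numpy(l1n, l2, c2)
        logits = l2n @ self.out.w.data + self.out.b.data
        return l1n, l2n, c1n, c2n, logits


def _transpose(t: Tensor) -> Tensor:
    out_data = t.data.T

    def backward(g):
        if t.requires_grad:
            t._accum(g.T)

    return Tensor._make(out_data, (t,), backward, t.requires_grad)


def _segment_softmax(scores: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    smax = np.full((n_seg,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(smax, seg, scores.data)
    shifted = scores - Tensor(smax[seg])
    e = shifted.exp()
    denom = segment_sum(e, seg, n_seg)
    return e * gather_rows(denom, seg) ** -1.0


def _wishlist_matrix(wishlists, n_graphs: int, model: GeneratorModel) -> np.ndarray | None:
    if wishlists is None:
        return None
    if isinstance(wishlists, PropertyWishlist) or (
        isinstance(wishlists, np.ndarray) and wishlists.ndim == 1
    ):
        wishlists = [wishlists]
    rows = []
    for w in wishlists:
        arr = w.as_array() if isinstance(w, PropertyWishlist) else np.asarray(w, float)
        if arr.shape != (6,):
            raise ValueError("wishlist must provide all six properties")
        rows.append(model.standardize_properties(arr))
    if len(rows) != n_graphs:
        raise ValueError("one wishlist per graph required")
    return np.stack(rows)


def _batch_graphs(graphs, mode: str) -> dict:
    """Pack a list of graphs into flat node/edge arrays with graph ids."""
    offsets, graph_ids = [], []
    recv, send = [], []
    n = 0
    for gi, g in enumerate(graphs):
        offsets.append(n)
        graph_ids.extend([gi] * g.n_atoms)
        for i, j in np.asarray(g.edges).reshape(-1, 2):
            recv.extend([n + i, n + j])  # both directions: j->i and i->j
            send.extend([n + j, n + i])
        n += g.n_atoms
    batch = {
        "n_nodes": n,
        "n_graphs": len(graphs),
        "graph_ids": np.array(graph_ids, dtype=np.intp),
        "recv": np.array(recv, dtype=np.intp),
        "send": np.array(send, dtype=np.intp),
    }
    if mode == "ligand":
        for name, attr in [
            ("atom_type", "atom_type_idx"),
            ("ring", "ring_flag"),
            ("arom", "aromatic_flag"),
            ("hyb", "hybridization_idx"),
        ]:
            batch[name] = np.concatenate([np.asarray(getattr(g, attr)) for g in graphs])
    else:
        batch["elem"] = np.concatenate([g.element_idx for g in graphs])
        batch["aa"] = np.concatenate([g.aa_atom_idx for g in graphs])
        batch["dist"] = np.concatenate([g.dist_to_ligand for g in graphs])
        batch["b_factor"] = np.concatenate([g.b_factor for g in graphs])
        width = 2 * graphs[0].n_freq
        fouriers = [
            np.repeat(g.edge_fourier.reshape(-1, width), 2, axis=0) for g in graphs
        ]  # row order matches the directed-edge interleaving above
        batch["fourier"] = (
            np.concatenate(fouriers) if fouriers else np.zeros((0, width))
        )
    return batch


# -- training ----------------------------------------------------------------


def train_generator(
    model: GeneratorModel,
    examples: list[tuple],
    epochs: int = 20,
    lr: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
    callback=None,
) -> list[float]:
    """Teacher-forced training; returns the per-epoch mean loss trace.

    `examples` holds (input_graph, output_smiles, wishlist-or-None) triples.
    Fully reproducible under a fixed seed; aborts with diagnostics if the
    loss turns non-finite.
    """
    rng = np.random.default_rng(seed)
    tokenized = [np.array(tokenize(s, model.alphabet)) for _g, s, _w in examples]
    max_len = max(len(t) for t in tokenized)
    pad = model.alphabet.pad_idx
    token_matrix = np.full((len(examples), max_len), pad, dtype=np.intp)
    for i, t in enumerate(tokenized):
        token_matrix[i, : len(t)] = t

    opt = Adam(model.parameters(), lr=lr)
    trace: list[float] = []
    n = len(examples)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            graphs = [examples[i][0] for i in idx]
            wish = [examples[i][2] for i in idx] if model.config.conditioned else None
            l1, l2 = model.encode(list(graphs), wish)
            loss = model.teacher_forced_loss(l1, l2, token_matrix[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: {float(loss.data)}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        trace.append(epoch_loss / n_batches)
        if callback is not None:
            callback(epoch, trace[-1])
    return trace


# -- sampling ----------------------------------------------------------------


def temperature_probs(logits: np.ndarray, T: float) -> np.ndarray:
    """Temperature-scaled softmax; invariant to additive shifts of the logits."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    z = np.asarray(logits, dtype=float) / T
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class SampledString:
    string: str
    valid: bool
    canonical: str | None


def sample(
    model: GeneratorModel,
    graph,
    wishlist=None,
    T: float = 0.5,
    n: int = 100,
    max_len: int | None = None,
    seed: int = 0,
) -> list[SampledString]:
    """Draw `n` strings by temperature sampling from the trained model.

    Invalid strings are data, not errors: each output carries a validity flag
    from the molecular parser (SMILES mode) and its canonical form if valid.
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    max_len = max_len or model.config.max_len
    rng = np.random.default_rng(seed)
    l1, l2 = model.encode(graph, wishlist if model.config.conditioned else None)
    l1 = np.repeat(l1.data, n, axis=0)
    l2 = np.repeat(l2.data, n, axis=0)
    c1 = np.zeros_like(l1)
    c2 = np.zeros_like(l2)
    alive = np.ones(n, dtype=bool)
    prev = np.full(n, model.alphabet.start_idx, dtype=np.intp)
    sequences: list[list[int]] = [[] for _ in range(n)]
    V = model.alphabet.size
    end, pad = model.alphabet.end_idx, model.alphabet.pad_idx
    for _ in range(max_len):
        l1, l2, c1, c2, logits = model.decode_step(l1, l2, c1, c2, prev)
        probs = temperature_probs(logits, T)
        u = rng.random((n, 1))
        nxt = (probs.cumsum(axis=1) < u).sum(axis=1).clip(0, V - 1)
        nxt = np.where(alive, nxt, pad)
        for i in np.nonzero(alive)[0]:
            if nxt[i] == end:
                alive[i] = False
            elif nxt[i] != pad and nxt[i] != model.alphabet.start_idx:
                sequences[i].append(int(nxt[i]))
        prev = np.where(alive, nxt, pad)
        if not alive.any():
            break
    out = []
    for seq in sequences:
        s = detokenize(seq, model.alphabet)
        if model.alphabet.representation == "smiles":
            canon = canonical_smiles(s)
            out.append(SampledString(s, canon is not None, canon))
        else:
            out.append(SampledString(s, True, None))
    return out


def sample_batch(
    model: GeneratorModel,
    graphs: list,
    wishlists=None,
    T: float = 0.5,
    max_len: int | None = None,
    seed: int = 0,
) -> list[SampledString]:
    """One temperature-sampled string per (graph, wishlist) pair.

    Batched counterpart of :func:`sample` for conditioned generation with a
    different wishlist per draw.
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    max_len = max_len or model.config.max_len
    rng = np.random.default_rng(seed)
    n = len(graphs)
    l1, l2 = model.encode(list(graphs), wishlists if model.config.conditioned else None)
    l1, l2 = l1.data, l2.data
    c1 = np.zeros_like(l1)
    c2 = np.zeros_like(l2)
    alive = np.ones(n, dtype=bool)
    prev = np.full(n, model.alphabet.start_idx, dtype=np.intp)
    sequences: list[list[int]] = [[] for _ in range(n)]
    V = model.alphabet.size
    end, pad = model.alphabet.end_idx, model.alphabet.pad_idx
    for _ in range(max_len):
        l1, l2, c1, c2, logits = model.decode_step(l1, l2, c1, c2, prev)
        probs = temperature_probs(logits, T)
        u = rng.random((n, 1))
        nxt = (probs.cumsum(axis=1) < u).sum(axis=1).clip(0, V - 1)
        nxt = np.where(alive, nxt, pad)
        for i in np.nonzero(alive)[0]:
            if nxt[i] == end:
                alive[i] = False
            elif nxt[i] >= 3:
                sequences[i].append(int(nxt[i]))
        prev = np.where(alive, nxt, pad)
        if not alive.any():
            break
    out = []
    for seq in sequences:
        s = detokenize(seq, model.alphabet)
        if model.alphabet.representation == "smiles":
            canon = canonical_smiles(s)
            out.append(SampledString(s, canon is not None, canon))
        else:
            out.append(SampledString(s, True, None))
    return out


def greedy_decode(model: GeneratorModel, graph, wishlist=None, max_len: int | None = None) -> str:
    """Argmax decoding (the T -> 0 limit); used for memorization checks."""
    max_len = max_len or model.config.max_len
    l1, l2 = model.encode(graph, wishlist if model.config.conditioned else None)
    l1, l2 = l1.data, l2.data
    c1 = np.zeros_like(l1)
    c2 = np.zeros_like(l2)
    prev = np.array([model.alphabet.start_idx])
    seq: list[int] = []
    for _ in range(max_len):
        l1, l2, c1, c2, logits = model.decode_step(l1, l2, c1, c2, prev)
        nxt = int(np.argmax(logits[0]))
        if nxt == model.alphabet.end_idx:
            break
        if nxt >= 3:
            seq.append(nxt)
        prev = np.array([nxt])
    return detokenize(seq, model.alphabet)


# -- accounting / persistence -------------------------------------------------


def count_parameters(model: GeneratorModel) -> tuple[int, int, int]:
    """(encoder, decoder, total) trainable-parameter counts."""
    enc = sum(m.n_parameters() for m in model.encoder_modules()) + model.pool_seeds.data.size
    dec = sum(m.n_parameters() for m in model.decoder_modules())
    return int(enc), int(dec), int(enc + dec)


def save_model(model: GeneratorModel, path) -> None:
    """Single-file artifact: weights + JSON metadata (dims, alphabet, stats, seed)."""
    meta = {
        "config": asdict(model.config),
        "alphabet": model.alphabet.to_dict(),
        "prop_mean": model.prop_mean.tolist(),
        "prop_std": model.prop_std.tolist(),
        "seed": model.seed,
    }
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> GeneratorModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    model = GeneratorModel(
        GeneratorConfig(**meta["config"]),
        TokenAlphabet.from_dict(meta["alphabet"]),
        seed=meta["seed"],
        prop_mean=np.array(meta["prop_mean"]),
        prop_std=np.array(meta["prop_std"]),
    )
    n = len([k for k in data.files if k.startswith("p")])
    model.load_state_arrays([data[f"p{i}"] for i in range(n)])
    return model
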