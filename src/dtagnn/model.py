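"""Model assembly: drug branch + protein branch + regression head.

Two variants share the protein branch and the head and differ in the second
graph layer of the drug branch:

* ``dual-attention`` (alias ``AL``) — both graph layers are dynamic
  attention;
* ``attention-gcn`` (alias ``CL``) — dynamic attention followed by a GCN
  layer.

The drug branch is layer 1 → ReLU → layer 2 → ReLU → global max pool →
linear projection; the protein branch is embedding → Bi-LSTM → 1D conv
encoder; the two fixed-width vectors are concatenated and passed through a
fully connected head ending in one scalar affinity per pair.  With the head
reduced to a single linear layer the model is exactly
``y = W_output [D, P] + b_output``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Linear, Module, Tensor, concat
from ._nn import dropout as _dropout
from .errors import ConfigError, InputError
from .graph_layers import DynamicGraphAttention, GraphConvolution, global_max_pool
from .molgraph import AtomFeatureSpec, MolecularGraph, smiles_to_graph
from .protseq import EncodedProtein, ProteinVocab, encode_protein
from .seq_layers import BiLSTM, Embedding, ProteinConvEncoder

__all__ = [
    "ModelConfig",
    "AffinityModel",
    "PairBatch",
    "FeaturizedDataset",
    "build_model",
    "forward",
    "predict_batch",
    "featurize_records",
    "save_model",
    "load_model",
    "config_to_dict",
    "config_from_dict",
]

_VARIANT_ALIASES = {
    "al": "dual-attention",
    "dual-attention": "dual-attention",
    "cl": "attention-gcn",
    "attention-gcn": "attention-gcn",
}


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults follow the published setup.

    The two graph layers default to widths (F, 2F) where F is the atom
    feature width, with 10 attention heads each and LeakyReLU slope 0.2;
    both branches project to 128 so the concatenation is balanced; the head
    is 256 → 1024 → 512 → 1 with dropout 0.2 after each hidden stage.
    """

    variant: str = "dual-attention"
    atom_feature_spec: AtomFeatureSpec = field(default_factory=AtomFeatureSpec)
    graph_width_1: int | None = None  # default: F
    graph_width_2: int | None = None  # default: 2F
    heads_1: int = 10
    heads_2: int = 10
    leaky_slope: float = 0.2
    drug_embed_width: int = 128
    protein_vocab: ProteinVocab = field(default_factory=ProteinVocab)
    protein_embed_dim: int = 128
    lstm_hidden: int = 10
    conv_channels: tuple[int, ...] = (32, 64, 96)
    conv_kernel: int = 8
    protein_embed_width: int = 128
    max_len: int = 1000
    fc_hidden: tuple[int, ...] = (1024, 512)
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        key = self.variant.lower()
        if key not in _VARIANT_ALIASES:
            raise ConfigError(
                f"unknown variant {self.variant!r}; "
                "expected 'dual-attention'/'AL' or 'attention-gcn'/'CL'"
            )
        self.variant = _VARIANT_ALIASES[key]
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")

    @property
    def feature_width(self) -> int:
        return self.atom_feature_spec.feature_width

    @classmethod
    def desk_scale(cls, variant: str = "dual-attention", seed: int = 0) -> "ModelConfig":
        """Reduced-width configuration used for CPU-scale experiments."""
        return cls(
            variant=variant,
            graph_width_1=32,
            graph_width_2=64,
            heads_1=2,
            heads_2=2,
            drug_embed_width=64,
            protein_embed_dim=16,
            lstm_hidden=8,
            conv_channels=(16, 16),
            conv_kernel=4,
            protein_embed_width=64,
            max_len=150,
            fc_hidden=(128, 64),
            dropout_rate=0.0,
            seed=seed,
        )


@dataclass
class PairBatch:
    """A batch of pairs with deduplicated structures.

    Graphs are merged into one disjoint union; ``drug_index`` /
    ``protein_index`` map each pair row to its unique structure, so each
    distinct molecule and protein is encoded once per forward pass.
    """

    node_features: np.ndarray  # (N_total, F)
    edge_index: np.ndarray  # (E_total, 2), node indices offset per graph
    node_graph: np.ndarray  # (N_total,) graph membership
    num_graphs: int
    protein_codes: np.ndarray  # (U, max_len)
    drug_index: np.ndarray  # (n_pairs,) -> graph id
    protein_index: np.ndarray  # (n_pairs,) -> protein row
    labels: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.drug_index)


class FeaturizedDataset:
    """Featurize records once; emit merged :class:`PairBatch` views on demand."""

    def __init__(self, records, config: ModelConfig):
        if not records:
            raise InputError("no records to featurize")
        self.config = config
        smiles_seen: dict[str, int] = {}
        seq_seen: dict[str, int] = {}
        self.graphs: list[MolecularGraph] = []
        self.codes: list[np.ndarray] = []
        self.pair_graph: list[int] = []
        self.pair_protein: list[int] = []
        self.records = list(records)
        for rec in self.records:
            if rec.smiles not in smiles_seen:
                smiles_seen[rec.smiles] = len(self.graphs)
                self.graphs.append(
                    smiles_to_graph(rec.smiles, config.atom_feature_spec, rec.drug_id)
                )
            if rec.sequence not in seq_seen:
                seq_seen[rec.sequence] = len(self.codes)
                self.codes.append(
                    encode_protein(
                        rec.sequence, config.protein_vocab, config.max_len,
                        rec.protein_id,
                    ).codes
                )
            self.pair_graph.append(smiles_seen[rec.smiles])
            self.pair_protein.append(seq_seen[rec.sequence])
        self.labels = np.array([r.affinity for r in self.records], dtype=np.float64)

    def batch(self, indices=None) -> PairBatch:
        if indices is None:
            indices = np.arange(len(self.records))
        indices = np.asarray(indices, dtype=np.intp)
        graph_ids = sorted({self.pair_graph[i] for i in indices})
        prot_ids = sorted({self.pair_protein[i] for i in indices})
        graph_pos = {g: k for k, g in enumerate(graph_ids)}
        prot_pos = {p: k for k, p in enumerate(prot_ids)}
        feats, edges, membership = [], [], []
        offset = 0
        for k, g in enumerate(graph_ids):
            graph = self.graphs[g]
            feats.append(graph.node_features)
            if graph.edge_index.size:
                edges.append(graph.edge_index + offset)
            membership.append(np.full(graph.num_nodes, k, dtype=np.int64))
            offset += graph.num_nodes
        return PairBatch(
            node_features=np.concatenate(feats, axis=0),
            edge_index=(
                np.concatenate(edges, axis=0)
                if edges
                else np.empty((0, 2), dtype=np.int64)
            ),
            node_graph=np.concatenate(membership),
            num_graphs=len(graph_ids),
            protein_codes=np.stack([self.codes[p] for p in prot_ids]),
            drug_index=np.array([graph_pos[self.pair_graph[i]] for i in indices]),
            protein_index=np.array([prot_pos[self.pair_protein[i]] for i in indices]),
            labels=self.labels[indices],
        )


class AffinityModel(Module):
    """The assembled two-branch regressor."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.feature_width
        w1 = config.graph_width_1 or f
        w2 = config.graph_width_2 or 2 * f
        relu = Tensor.relu
        self.gat1 = DynamicGraphAttention(
            f, w1, rng, heads=config.heads_1, leaky_slope=config.leaky_slope,
            dropout_rate=config.dropout_rate, activation=relu,
        )
        if config.variant == "dual-attention":
            self.graph2 = DynamicGraphAttention(
                w1, w2, rng, heads=config.heads_2, leaky_slope=config.leaky_slope,
                dropout_rate=config.dropout_rate, activation=relu,
            )
        else:  # attention-gcn
            self.graph2 = GraphConvolution(w1, w2, rng, activation=relu)
        self.drug_proj = Linear(w2, config.drug_embed_width, rng)
        self.embedding = Embedding(
            config.protein_vocab.size + 1, config.protein_embed_dim, rng
        )
        self.bilstm = BiLSTM(config.protein_embed_dim, config.lstm_hidden, rng)
        self.conv_encoder = ProteinConvEncoder(
            2 * config.lstm_hidden, rng, channels=config.conv_channels,
            kernel=config.conv_kernel, out_dim=config.protein_embed_width,
        )
        head_in = config.drug_embed_width + config.protein_embed_width
        self.head: list[Linear] = []
        for width in config.fc_hidden:
            self.head.append(Linear(head_in, width, rng))
            head_in = width
        self.output = Linear(head_in, 1, rng)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0x5EED])
        )

    # -- branches ----------------------------------------------------------
    def drug_vectors(self, batch: PairBatch, training: bool = False) -> Tensor:
        x = Tensor(batch.node_features)
        rng = self._dropout_rng
        h = self.gat1(x, batch.edge_index, training=training, rng=rng)
        h = self.graph2(h, batch.edge_index, training=training, rng=rng)
        pooled = global_max_pool(h, batch.node_graph, batch.num_graphs)
        return self.drug_proj(pooled)

    def protein_vectors(self, batch: PairBatch) -> Tensor:
        emb = self.embedding(batch.protein_codes)
        p_matrix = self.bilstm(emb, batch.protein_codes)
        return self.conv_encoder(p_matrix)

    def forward_batch(self, batch: PairBatch, training: bool = False) -> Tensor:
        """Predicted affinity for each pair row, shape (n_pairs,)."""
        from ._nn import rows

        drug = rows(self.drug_vectors(batch, training), batch.drug_index)
        prot = rows(self.protein_vectors(batch), batch.protein_index)
        h = concat([drug, prot], axis=1)
        for layer in self.head:
            h = layer(h).relu()
            if training and self.config.dropout_rate > 0:
                h = _dropout(h, self.config.dropout_rate, self._dropout_rng)
        return self.output(h).reshape(len(batch))


def build_model(config: ModelConfig) -> AffinityModel:
    """Build a model with seeded, reproducible initialization."""
    return AffinityModel(config)


def forward(
    model: AffinityModel, graph: MolecularGraph, protein: EncodedProtein
) -> float:
    """Evaluation-mode prediction for one (drug, protein) pair."""
    if graph.node_features.shape[1] != model.config.feature_width:
        raise InputError("graph feature width does not match model config")
    batch = PairBatch(
        node_features=graph.node_features,
        edge_index=graph.edge_index,
        node_graph=np.zeros(graph.num_nodes, dtype=np.int64),
        num_graphs=1,
        protein_codes=protein.codes[None, :],
        drug_index=np.zeros(1, dtype=np.intp),
        protein_index=np.zeros(1, dtype=np.intp),
    )
    return float(model.forward_batch(batch, training=False).data[0])


def predict_batch(
    model: AffinityModel, records, strict: bool = True
) -> pd.DataFrame:
    """Predict affinities for a record list → DataFrame, order preserved.

    In permissive mode featurization failures yield NaN predictions with the
    error message in an ``error`` column instead of aborting the batch.
    """
    if not records:
        raise InputError("no records to predict")
    rows_out = []
    ok_indices, ok_records = [], []
    for i, rec in enumerate(records):
        rows_out.append(
            {"drug_id": rec.drug_id, "protein_id": rec.protein_id,
             "affinity_pred": np.nan, "error": ""}
        )
        try:
            smiles_to_graph(rec.smiles, model.config.atom_feature_spec)
            if not rec.sequence:
                raise InputError("empty sequence")
        except Exception as exc:  # noqa: BLE001 - reported per row
            if strict:
                raise
            rows_out[-1]["error"] = str(exc)
            continue
        ok_indices.append(i)
        ok_records.append(rec)
    dataset = FeaturizedDataset(ok_records, model.config)
    preds = model.forward_batch(dataset.batch(), training=False).data
    for i, p in zip(ok_indices, preds):
        rows_out[i]["affinity_pred"] = float(p)
    return pd.DataFrame(rows_out)


def featurize_records(records, config: ModelConfig) -> FeaturizedDataset:
    return FeaturizedDataset(records, config)


# --------------------------------------------------------------------------
# checkpoint serialization (config embedded alongside the weights)


def config_to_dict(config: ModelConfig) -> dict:
    return {
        "variant": config.variant,
        "atom_feature_spec": {
            "symbol_vocab": list(config.atom_feature_spec.symbol_vocab),
            "max_degree": config.atom_feature_spec.max_degree,
            "max_num_h": config.atom_feature_spec.max_num_h,
            "max_implicit_valence": config.atom_feature_spec.max_implicit_valence,
            "include_aromatic_flag": config.atom_feature_spec.include_aromatic_flag,
        },
        "graph_width_1": config.graph_width_1,
        "graph_width_2": config.graph_width_2,
        "heads_1": config.heads_1,
        "heads_2": config.heads_2,
        "leaky_slope": config.leaky_slope,
        "drug_embed_width": config.drug_embed_width,
        "protein_vocab": {
            "alphabet": config.protein_vocab.alphabet,
            "unknown": config.protein_vocab.unknown,
        },
        "protein_embed_dim": config.protein_embed_dim,
        "lstm_hidden": config.lstm_hidden,
        "conv_channels": list(config.conv_channels),
        "conv_kernel": config.conv_kernel,
        "protein_embed_width": config.protein_embed_width,
        "max_len": config.max_len,
        "fc_hidden": list(config.fc_hidden),
        "dropout_rate": config.dropout_rate,
        "seed": config.seed,
    }


def config_from_dict(payload: dict) -> ModelConfig:
    payload = dict(payload)
    spec = payload.get("atom_feature_spec")
    if isinstance(spec, dict):
        spec = dict(spec)
        spec["symbol_vocab"] = tuple(spec["symbol_vocab"])
        payload["atom_feature_spec"] = AtomFeatureSpec(**spec)
    vocab = payload.get("protein_vocab")
    if isinstance(vocab, dict):
        payload["protein_vocab"] = ProteinVocab(**vocab)
    for key in ("conv_channels", "fc_hidden"):
        if key in payload and payload[key] is not None:
            payload[key] = tuple(payload[key])
    known = set(ModelConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return ModelConfig(**payload)


def save_model(model: AffinityModel, path) -> None:
    """Serialize weights + config to a single .npz checkpoint."""
    import json

    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(config_to_dict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> AffinityModel:
    import json

    with np.load(path) as payload:
        config = config_from_dict(
            json.loads(bytes(payload["config_json"].tolist()).decode())
        )
        model = build_model(config)
        params = model.parameters()
        for i, p in enumerate(params):
            stored = payload[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ConfigError("checkpoint/config shape mismatch")
            p.data = stored.astype(np.float64)
    return model
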