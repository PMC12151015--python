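"""Per-residue embedding providers.

Three producers share one contract: a transformer sequence model (ESM-2,
1280-wide per-token representations), an inverse-folding structural
encoder (ESM-IF1, 512-wide) and a deterministic mock backend used for
offline development and testing.  Every provider returns an
:class:`EmbeddingMatrix` whose rows are aligned with the complex's
residue order — the contract downstream pooling relies on.

The real backends need the optional ``fair-esm``/``torch`` dependencies
and multi-GB checkpoints; when absent they raise
:class:`ProviderUnavailableError` with install instructions.  The mock
backend is a pure function of (residue letter, chain, position, seed):
two calls with the same arguments are bitwise identical, and a point
mutation perturbs exactly one row.  Real transformer embeddings are not
local in this sense and nothing downstream may assume they are.
"""

from __future__ import annotations

import functools
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .dataset import AA20, ChainSequence, ComplexStructure

logger = logging.getLogger(__name__)

SEQUENCE_WIDTH = 1280
STRUCTURE_WIDTH = 512

PROVIDER_KINDS = ("sequence", "structure", "mock_sequence", "mock_structure")
_KIND_WIDTHS = {
    "sequence": SEQUENCE_WIDTH,
    "mock_sequence": SEQUENCE_WIDTH,
    "structure": STRUCTURE_WIDTH,
    "mock_structure": STRUCTURE_WIDTH,
}

DEFAULT_SEQUENCE_CHECKPOINT = "esm2_t33_650M_UR50D"
DEFAULT_STRUCTURE_CHECKPOINT = "esm_if1_gvp4_t16_142M_UR50"


class ProviderUnavailableError(RuntimeError):
    """A real embedding backend (or its checkpoint) is not installed."""


@dataclass(frozen=True)
class ProviderInfo:
    """Identity and width of an embedding producer."""

    name: str
    kind: str
    width: int
    checkpoint_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in PROVIDER_KINDS:
            raise ValueError(f"kind must be one of {PROVIDER_KINDS}, got {self.kind!r}")
        if self.width <= 0:
            raise ValueError("width must be positive")
        expected = _KIND_WIDTHS[self.kind]
        if self.width != expected:
            raise ValueError(
                f"{self.kind} providers are {expected}-wide, got width {self.width}"
            )

    @property
    def is_mock(self) -> bool:
        return self.kind.startswith("mock_")

    @property
    def mock_seed(self) -> int:
        if not self.checkpoint_id.startswith("seed:"):
            return 0
        return int(self.checkpoint_id.split(":", 1)[1])


def esm2_provider(checkpoint: str = DEFAULT_SEQUENCE_CHECKPOINT) -> ProviderInfo:
    return ProviderInfo("esm2", "sequence", SEQUENCE_WIDTH, checkpoint)


def esm_if1_provider(checkpoint: str = DEFAULT_STRUCTURE_CHECKPOINT) -> ProviderInfo:
    return ProviderInfo("esm-if1", "structure", STRUCTURE_WIDTH, checkpoint)


def mock_sequence_provider(seed: int = 0) -> ProviderInfo:
    return ProviderInfo("mock-seq", "mock_sequence", SEQUENCE_WIDTH, f"seed:{seed}")


def mock_structure_provider(seed: int = 0) -> ProviderInfo:
    return ProviderInfo("mock-struct", "mock_structure", STRUCTURE_WIDTH, f"seed:{seed}")


@dataclass(frozen=True)
class EmbeddingMatrix:
    """L per-residue rows of width d, labelled by (chain_id, position)."""

    rows: np.ndarray
    residue_index: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.float64)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "residue_index", tuple(self.residue_index))
        if rows.ndim != 2 or rows.shape[0] < 1:
            raise ValueError(f"rows must be a non-empty 2-D array, got shape {rows.shape}")
        if len(self.residue_index) != rows.shape[0]:
            raise ValueError(
                f"{len(self.residue_index)} residue labels for {rows.shape[0]} rows"
            )

    @property
    def length(self) -> int:
        return self.rows.shape[0]

    @property
    def width(self) -> int:
        return self.rows.shape[1]


# ---------------------------------------------------------------------------
# mock backend
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1 << 16)
def _mock_row(letter: str, chain_id: str, position: str, seed: int, width: int) -> np.ndarray:
    # blake2b gives a stable cross-process stream seed; python's hash() would not.
    key = f"{letter}|{chain_id}|{position}|{seed}|{width}".encode()
    stream = int.from_bytes(hashlib.blake2b(key, digest_size=8).digest(), "big")
    rng = np.random.Generator(np.random.PCG64(stream))
    row = rng.uniform(-1.0, 1.0, size=width)
    row.setflags(write=False)
    return row


def mock_embed(
    tokens: Sequence[tuple[str, str, str]], width: int, seed: int = 0
) -> EmbeddingMatrix:
    """Deterministic stand-in embedding.

    ``tokens`` are (chain_id, position, residue letter) triples.  Row i is a
    pure function of its token and the seed, with entries in [−1, 1]; changing
    one residue letter changes exactly that row.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    rows = np.stack([
        _mock_row(letter, chain_id, str(position), int(seed), int(width))
        for chain_id, position, letter in tokens
    ])
    return EmbeddingMatrix(rows, tuple((c, str(p)) for c, p, _ in tokens))


def _chain_tokens(chains: Iterable[ChainSequence]) -> list[tuple[str, str, str]]:
    return [
        (c.chain_id, pos, letter)
        for c in chains
        for pos, letter in zip(c.numbering, c.sequence)
    ]


# ---------------------------------------------------------------------------
# provider front-ends
# ---------------------------------------------------------------------------

def embed_sequence(
    chains: Sequence[ChainSequence], provider: ProviderInfo
) -> EmbeddingMatrix:
    """Per-residue sequence embeddings for all chains, concatenated in chain order.

    Each chain is run through the model in its own forward pass and the
    backend's special/boundary tokens are excluded, so the returned matrix has
    exactly one row per residue.
    """
    if provider.kind not in ("sequence", "mock_sequence"):
        raise ValueError(f"provider kind {provider.kind!r} cannot embed sequences")
    chains = list(chains)
    if not chains or any(len(c) == 0 for c in chains):
        raise ValueError("all chains must be non-empty")
    for c in chains:
        bad = set(c.sequence) - AA20
        if bad:
            raise ValueError(
                f"chain {c.chain_id} contains letters outside the backend alphabet: {sorted(bad)}"
            )
    if provider.is_mock:
        return mock_embed(_chain_tokens(chains), provider.width, provider.mock_seed)
    return _esm2_embed(chains, provider)


def embed_structure(
    structure: ComplexStructure, provider: ProviderInfo
) -> EmbeddingMatrix:
    """Per-residue structural embeddings for both partners of a complex."""
    if provider.kind not in ("structure", "mock_structure"):
        raise ValueError(f"provider kind {provider.kind!r} cannot embed structures")
    for chain in structure.chains:
        coords = structure.backbone[chain.chain_id]
        if coords.shape[0] != len(chain):
            raise ValueError(
                f"chain {chain.chain_id}: {coords.shape[0]} coordinate rows for "
                f"{len(chain)} residues"
            )
    if provider.is_mock:
        return mock_embed(_chain_tokens(structure.chains), provider.width, provider.mock_seed)
    return _esm_if1_embed(structure, provider)


def _esm2_embed(chains: Sequence[ChainSequence], provider: ProviderInfo) -> EmbeddingMatrix:
    try:
        import esm  # type: ignore
        import torch  # type: ignore
    except ImportError as exc:  # pragma: no cover - needs optional heavy deps
        raise ProviderUnavailableError(
            "the ESM-2 sequence backend needs the optional dependencies "
            "`fair-esm` and `torch` (pip install probass[esm]); the checkpoint "
            f"{provider.checkpoint_id!r} is downloaded on first use"
        ) from exc
    # pragma: no cover — exercised only with the optional backend installed.
    model, alphabet = esm.pretrained.load_model_and_alphabet(provider.checkpoint_id)
    model.eval()
    converter = alphabet.get_batch_converter()
    final_layer = model.num_layers
    rows = []
    with torch.no_grad():
        for chain in chains:
            _, _, tokens = converter([(chain.chain_id, chain.sequence)])
            out = model(tokens, repr_layers=[final_layer])
            rep = out["representations"][final_layer][0]
            # drop BOS/EOS boundary tokens
            rows.append(rep[1:len(chain.sequence) + 1].cpu().numpy())
    matrix = np.concatenate(rows, axis=0)
    if matrix.shape[1] != provider.width:
        raise ProviderUnavailableError(
            f"checkpoint {provider.checkpoint_id!r} yields width {matrix.shape[1]}, "
            f"expected {provider.width}"
        )
    return EmbeddingMatrix(matrix, tuple((c.chain_id, p) for c in chains for p in c.numbering))


def _esm_if1_embed(structure: ComplexStructure, provider: ProviderInfo) -> EmbeddingMatrix:
    try:
        import esm  # type: ignore
        import esm.inverse_folding as inverse_folding  # type: ignore
        import torch  # type: ignore
    except ImportError as exc:  # pragma: no cover - needs optional heavy deps
        raise ProviderUnavailableError(
            "the ESM-IF1 structural backend needs the optional dependencies "
            "`fair-esm` and `torch` (pip install probass[esm]); the checkpoint "
            f"{provider.checkpoint_id!r} is downloaded on first use"
        ) from exc
    # pragma: no cover — exercised only with the optional backend installed.
    model, alphabet = esm.pretrained.load_model_and_alphabet(provider.checkpoint_id)
    model.eval()
    coords = {
        c.chain_id: structure.backbone[c.chain_id].astype(np.float32)
        for c in structure.chains
    }
    rows = []
    with torch.no_grad():
        for chain in structure.chains:
            rep = inverse_folding.multichain_util.get_encoder_output_for_complex(
                model, alphabet, coords, chain.chain_id
            )
            rows.append(rep.cpu().numpy())
    matrix = np.concatenate(rows, axis=0)
    if matrix.shape[1] != provider.width:
        raise ProviderUnavailableError(
            f"checkpoint {provider.checkpoint_id!r} yields width {matrix.shape[1]}, "
            f"expected {provider.width}"
        )
    return EmbeddingMatrix(matrix, structure.residue_index)


# ---------------------------------------------------------------------------
# on-disk cache
# ---------------------------------------------------------------------------

def input_digest(*parts: str) -> str:
    """Stable digest of canonical input descriptions (sequences, coordinates…)."""
    h = hashlib.sha256()
    for part in parts:
        h.update(part.encode())
        h.update(b"\x00")
    return h.hexdigest()[:24]


class EmbeddingCache:
    """One file per (provider, input digest); corrupt entries are recomputed."""

    _VERSION = 1

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, provider: ProviderInfo, digest: str) -> Path:
        safe = provider.name.replace("/", "_")
        return self.directory / f"{safe}-{provider.kind}-{digest}.npz"

    def get_or_compute(
        self,
        provider: ProviderInfo,
        digest: str,
        compute: Callable[[], EmbeddingMatrix],
    ) -> EmbeddingMatrix:
        path = self._path(provider, digest)
        if path.exists():
            try:
                with np.load(path, allow_pickle=False) as npz:
                    meta = json.loads(str(npz["meta"]))
                    if meta["version"] != self._VERSION or meta["width"] != provider.width:
                        raise ValueError("cache schema mismatch")
                    index = tuple(zip(npz["chain"].tolist(), npz["pos"].tolist()))
                    return EmbeddingMatrix(npz["rows"], index)
            except Exception as exc:
                logger.warning("corrupt cache entry %s (%s); recomputing", path, exc)
        matrix = compute()
        meta = json.dumps({
            "version": self._VERSION,
            "provider": provider.name,
            "kind": provider.kind,
            "width": provider.width,
            "checkpoint_id": provider.checkpoint_id,
        })
        np.savez(
            path,
            rows=matrix.rows,
            chain=np.array([c for c, _ in matrix.residue_index]),
            pos=np.array([p for _, p in matrix.residue_index]),
            meta=np.array(meta),
        )
        return matrix
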