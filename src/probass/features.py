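"""Per-mutation feature assembly.

Each mutation is described by 1792 numbers: the difference between the
mean-pooled sequence embedding of the mutant complex and that of the
wild type (1280 entries), followed by the mean-pooled wild-type
structural embedding (512 entries).  The structural block is computed
from the wild-type structure only — backbone coordinates barely move for
a point substitution, so the wild-type encoder output describes mutant
and wild type alike — which also means it is constant across all
mutations of one complex and can be cached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import (
    ChainSequence,
    ComplexStructure,
    MutationRecord,
    WtMismatchError,
    apply_mutation,
)
from .embeddings import (
    SEQUENCE_WIDTH,
    STRUCTURE_WIDTH,
    EmbeddingMatrix,
    ProviderInfo,
    embed_sequence,
    embed_structure,
)

logger = logging.getLogger(__name__)

FEATURE_WIDTH = SEQUENCE_WIDTH + STRUCTURE_WIDTH
#: Column names of the feature table, sequence block first.
FEATURE_COLUMNS = tuple(
    [f"seq_{i}" for i in range(SEQUENCE_WIDTH)] + [f"str_{i}" for i in range(STRUCTURE_WIDTH)]
)


def mean_pool(matrix: EmbeddingMatrix | np.ndarray) -> np.ndarray:
    """Arithmetic mean of the per-residue rows: one fixed-width vector."""
    rows = matrix.rows if isinstance(matrix, EmbeddingMatrix) else np.asarray(matrix)
    if rows.ndim != 2 or rows.shape[0] == 0:
        raise ValueError("cannot pool an empty embedding matrix")
    return rows.mean(axis=0)


def sequence_delta(pooled_mut: np.ndarray, pooled_wt: np.ndarray) -> np.ndarray:
    """Elementwise pooled mutant minus pooled wild type."""
    pooled_mut = np.asarray(pooled_mut)
    pooled_wt = np.asarray(pooled_wt)
    if pooled_mut.shape != pooled_wt.shape:
        raise ValueError(
            f"width mismatch: {pooled_mut.shape} vs {pooled_wt.shape}"
        )
    return pooled_mut - pooled_wt


@dataclass(frozen=True)
class FeatureVector:
    """The 1792-entry feature of one mutation: [sequence delta | WT structure]."""

    seq_delta: np.ndarray
    struct_wt: np.ndarray

    def __post_init__(self) -> None:
        sd = np.asarray(self.seq_delta, dtype=np.float64)
        sw = np.asarray(self.struct_wt, dtype=np.float64)
        object.__setattr__(self, "seq_delta", sd)
        object.__setattr__(self, "struct_wt", sw)
        if sd.shape != (SEQUENCE_WIDTH,):
            raise ValueError(f"sequence block must be {SEQUENCE_WIDTH}-wide, got {sd.shape}")
        if sw.shape != (STRUCTURE_WIDTH,):
            raise ValueError(f"structural block must be {STRUCTURE_WIDTH}-wide, got {sw.shape}")

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.seq_delta, self.struct_wt])

    def __len__(self) -> int:
        return FEATURE_WIDTH


class _ComplexCache(dict):
    """Per-complex memo of pooled WT sequence and structural embeddings."""


def _mutant_chains(
    chains: Sequence[ChainSequence], record: MutationRecord
) -> list[ChainSequence]:
    by_id = {c.chain_id: c for c in chains}
    for spec in record.mutations:
        if spec.chain_id not in by_id:
            raise KeyError(
                f"record {record.pdb_id} {record.mutation_string()}: "
                f"no chain {spec.chain_id} in complex"
            )
        by_id[spec.chain_id] = apply_mutation(by_id[spec.chain_id], spec)
    return [by_id[c.chain_id] for c in chains]


def assemble_features(
    record: MutationRecord,
    structure: ComplexStructure,
    seq_provider: ProviderInfo,
    struct_provider: ProviderInfo,
    cache: dict | None = None,
) -> FeatureVector:
    """Build one mutation's feature vector.

    The wild type and the mutant (with both substitutions applied together
    for a double mutant) each get one forward pass through the sequence
    model; pooling runs over all residues of both partners jointly.  The
    structural block comes from the wild-type structure only.  Pass a dict as
    ``cache`` to reuse the per-complex wild-type poolings across records.
    """
    cache = cache if cache is not None else {}
    wt_chains = list(structure.chains)

    key_wt = ("wt_seq", structure.pdb_id, seq_provider)
    if key_wt not in cache:
        cache[key_wt] = mean_pool(embed_sequence(wt_chains, seq_provider))
    pooled_wt = cache[key_wt]

    mut_chains = _mutant_chains(wt_chains, record)
    pooled_mut = mean_pool(embed_sequence(mut_chains, seq_provider))

    key_struct = ("wt_struct", structure.pdb_id, struct_provider)
    if key_struct not in cache:
        cache[key_struct] = mean_pool(embed_structure(structure, struct_provider))
    struct_wt = cache[key_struct]

    return FeatureVector(sequence_delta(pooled_mut, pooled_wt), struct_wt)


@dataclass
class FeaturizedDataset:
    """Aligned design matrix, targets and the records that produced them."""

    X: pd.DataFrame
    y: np.ndarray
    records: list[MutationRecord]
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.records)


def featurize_dataset(
    records: Iterable[MutationRecord],
    structures: Mapping[str, ComplexStructure],
    seq_provider: ProviderInfo,
    struct_provider: ProviderInfo,
) -> FeaturizedDataset:
    """Featurize a record list; rows follow record order.

    Wild-type poolings are computed once per complex and reused.  Records
    that fail assembly (wild-type mismatch, unknown chain/position) are
    skipped with a logged reason; an empty design matrix is an error.
    """
    cache: dict = {}
    rows: list[np.ndarray] = []
    kept: list[MutationRecord] = []
    skipped: list[tuple[int, str]] = []
    for i, record in enumerate(records):
        structure = structures.get(record.pdb_id)
        if structure is None:
            skipped.append((i, f"no structure for {record.pdb_id}"))
            logger.warning("record %d: no structure for %s", i, record.pdb_id)
            continue
        try:
            fv = assemble_features(record, structure, seq_provider, struct_provider, cache)
        except (WtMismatchError, KeyError, ValueError) as exc:
            skipped.append((i, str(exc)))
            logger.warning("record %d skipped: %s", i, exc)
            continue
        rows.append(fv.combined)
        kept.append(record)
    if not rows:
        raise ValueError("no record could be featurized: empty design matrix")
    X = pd.DataFrame(np.stack(rows), columns=list(FEATURE_COLUMNS))
    y = np.array(
        [np.nan if r.ddg_exp is None else r.ddg_exp for r in kept], dtype=np.float64
    )
    logger.info(
        "featurized %d records (%d skipped) over %d complexes",
        len(kept), len(skipped), len({r.pdb_id for r in kept}),
    )
    return FeaturizedDataset(X=X, y=y, records=kept, skipped=skipped)
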