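"""Synthetic complexes and mutation datasets with known ground truth.

The generator builds a toy two-chain complex with an interface, draws
unique single and double substitutions from its sequences, and assigns
ΔΔG targets as a sparse linear function of the mock-embedding features
plus Gaussian noise.  Because the true weights are known, downstream
training and evaluation can be checked against closed-form expectations
(fit capacity, noise-attenuation ceilings) entirely offline.

Default conditions mirror the shape of the experimental data the method
is aimed at: 2000 mutations (1600 single, 400 double) in one complex of
105 residues, 20 informative feature dimensions, noise SD at a quarter
of the signal SD, and a signal scaled so that targets span roughly the
±12 kcal/mol range observed for real single mutations.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dataset import (
    AA_ORDER,
    ONE_TO_THREE,
    ComplexStructure,
    MutationRecord,
    MutationSpec,
    load_complex,
    write_mutation_table,
)
from .embeddings import ProviderInfo, mock_sequence_provider, mock_structure_provider
from .features import FeaturizedDataset, featurize_dataset

#: Target standard deviation of the noiseless signal, kcal/mol.  Chosen so
#: that ±4 SD covers the ±12.3 kcal/mol range real single mutations span.
SIGNAL_SD_KCAL = 3.0

_CA_SPACING = 3.8  # Å along the chain axis
_CHAIN_GAP = 3.5   # Å between the two chain planes; paired with a 1.9 Å x-shift
                   # this puts facing Cα pairs at 3.98 Å — inside the 4 Å cutoff.


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic dataset."""

    n_res_a: int = 60
    n_res_b: int = 45
    n_single: int = 1600
    n_double: int = 400
    informative_dims: int = 20
    noise_sd: float | None = None      # absolute, kcal/mol
    noise_to_signal: float | None = 0.25  # used when noise_sd is None
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_res_a", "n_res_b", "n_single", "n_double", "informative_dims"):
            if getattr(self, name) < 0 or (name.startswith("n_res") and getattr(self, name) < 3):
                raise ValueError(f"{name} out of range")
        if self.n_single + self.n_double < 1:
            raise ValueError("need at least one mutation")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_toy_complex(config: FixtureConfig) -> tuple[str, tuple[set, set]]:
    """PDB-format text of a two-chain complex plus its partner specification.

    Chain A is a straight Cα trace along x; chain B runs parallel, shifted
    half a step along x and 3.5 Å in z, so every facing Cα pair sits at
    3.98 Å — at least one cross-partner contact is inside the 4 Å interface
    cutoff by construction.  Byte-identical output for the same seed.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    rng = np.random.default_rng(config.seed)
    letters = list(AA_ORDER)
    seq_a = "".join(rng.choice(letters, size=config.n_res_a))
    seq_b = "".join(rng.choice(letters, size=config.n_res_b))

    n_atoms = 3 * (config.n_res_a + config.n_res_b)
    atoms = struc.AtomArray(n_atoms)
    i = 0
    for chain_id, seq, z in (("A", seq_a, 0.0), ("B", seq_b, _CHAIN_GAP)):
        x_shift = 0.0 if chain_id == "A" else _CA_SPACING / 2
        for res_i, letter in enumerate(seq):
            ca = np.array([_CA_SPACING * res_i + x_shift, 0.0, z])
            for atom_name, offset in (
                ("N", np.array([-1.2, 0.8, 0.0])),
                ("CA", np.zeros(3)),
                ("C", np.array([1.2, 0.8, 0.0])),
            ):
                atoms.chain_id[i] = chain_id
                atoms.res_id[i] = res_i + 1
                atoms.res_name[i] = ONE_TO_THREE[letter]
                atoms.atom_name[i] = atom_name
                atoms.element[i] = atom_name[0]
                atoms.hetero[i] = False
                atoms.coord[i] = ca + offset
                i += 1
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(atoms)
    buffer = io.StringIO()
    pdb_file.write(buffer)
    return buffer.getvalue(), ({"A"}, {"B"})


def make_mutation_set(
    structure: ComplexStructure, n_single: int, n_double: int, seed: int = 0
) -> list[MutationRecord]:
    """Unique mutation records consistent with the complex sequences, ΔΔG unset."""
    rng = np.random.default_rng(seed)
    sites = [
        (c.chain_id, pos, wt)
        for c in structure.chains
        for pos, wt in zip(c.numbering, c.sequence)
    ]
    singles_all = [
        (chain, pos, wt, mut)
        for chain, pos, wt in sites
        for mut in AA_ORDER
        if mut != wt
    ]
    if n_single > len(singles_all):
        raise ValueError(
            f"{n_single} unique single mutations requested, only {len(singles_all)} possible"
        )
    chosen = rng.choice(len(singles_all), size=n_single, replace=False)
    records = [
        MutationRecord(
            pdb_id=structure.pdb_id,
            mutations=(MutationSpec(chain, pos, wt, mut),),
            ddg_exp=None,
        )
        for chain, pos, wt, mut in (singles_all[int(i)] for i in chosen)
    ]

    seen: set[frozenset] = set()
    max_doubles = len(sites) * (len(sites) - 1) // 2 * 19 * 19
    if n_double > max_doubles:
        raise ValueError(f"{n_double} double mutations infeasible for {len(sites)} sites")
    attempts = 0
    while sum(r.is_double for r in records) < n_double:
        attempts += 1
        if attempts > 100 * max(n_double, 1):
            raise ValueError("could not draw enough unique double mutations")
        i, j = rng.choice(len(sites), size=2, replace=False)
        specs = []
        for chain, pos, wt in (sites[int(i)], sites[int(j)]):
            mut = AA_ORDER[int(rng.integers(20))]
            if mut == wt:
                break
            specs.append(MutationSpec(chain, pos, wt, mut))
        if len(specs) != 2:
            continue
        key = frozenset(s.token() for s in specs)
        if key in seen:
            continue
        seen.add(key)
        records.append(MutationRecord(
            pdb_id=structure.pdb_id, mutations=tuple(specs), ddg_exp=None,
        ))
    return records


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a synthetic target vector."""

    targets: np.ndarray
    weights: np.ndarray           # full-width, sparse
    informative_idx: np.ndarray
    signal_sd: float
    noise_sd: float
    seed: int


def make_synthetic_ddg(
    X: np.ndarray,
    informative_dims: int,
    noise_sd: float | None = None,
    noise_to_signal: float | None = None,
    seed: int = 0,
    signal_sd: float = SIGNAL_SD_KCAL,
) -> SyntheticTruth:
    """Draw sparse linear targets: y = X·w + ε, ε ~ N(0, noise_sd²).

    The sparse weight vector is rescaled so the realized noiseless signal has
    standard deviation ``signal_sd`` kcal/mol.  ``noise_to_signal`` sets the
    noise relative to that SD when no absolute ``noise_sd`` is given.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D feature matrix")
    n, d = X.shape
    if not 1 <= informative_dims <= d:
        raise ValueError(f"informative_dims must be in [1, {d}]")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(d, size=informative_dims, replace=False))
    w0 = rng.normal(size=informative_dims)
    signal0 = X[:, idx] @ w0
    sd0 = signal0.std()
    if sd0 == 0:
        raise ValueError("degenerate features: the drawn signal has zero variance")
    scale = signal_sd / sd0
    weights = np.zeros(d)
    weights[idx] = w0 * scale
    signal = signal0 * scale
    if noise_sd is None:
        noise_sd = (noise_to_signal or 0.0) * signal_sd
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    return SyntheticTruth(
        targets=signal + eps,
        weights=weights,
        informative_idx=idx,
        signal_sd=float(signal_sd),
        noise_sd=float(noise_sd),
        seed=seed,
    )


def attach_targets(
    records: list[MutationRecord], targets: np.ndarray, ddg_error: float | None = None
) -> list[MutationRecord]:
    if len(records) != len(targets):
        raise ValueError("records and targets differ in length")
    return [
        replace(r, ddg_exp=float(t), ddg_error=ddg_error)
        for r, t in zip(records, targets)
    ]


@dataclass
class SyntheticFixture:
    """Everything a fully offline pipeline run needs, with ground truth."""

    config: FixtureConfig
    pdb_text: str
    partner_spec: tuple[set, set]
    structure: ComplexStructure
    records: list[MutationRecord]
    dataset: FeaturizedDataset
    truth: SyntheticTruth
    seq_provider: ProviderInfo
    struct_provider: ProviderInfo


def generate_fixture(
    config: FixtureConfig | None = None,
    tmp_dir: str | Path | None = None,
) -> SyntheticFixture:
    """Full generator: toy complex → mutations → mock features → linear ΔΔG.

    The PDB text round-trips through the regular structure loader so the
    fixture exercises the same code paths as real data.
    """
    import tempfile

    config = config or FixtureConfig()
    pdb_text, partner_spec = make_toy_complex(config)
    if tmp_dir is None:
        with tempfile.TemporaryDirectory() as td:
            pdb_path = Path(td) / "toy.pdb"
            pdb_path.write_text(pdb_text)
            structure = load_complex(pdb_path, partner_spec)
    else:
        pdb_path = Path(tmp_dir) / "toy.pdb"
        pdb_path.write_text(pdb_text)
        structure = load_complex(pdb_path, partner_spec)

    records = make_mutation_set(structure, config.n_single, config.n_double, seed=config.seed)
    seq_provider = mock_sequence_provider(seed=config.seed)
    struct_provider = mock_structure_provider(seed=config.seed)
    dataset = featurize_dataset(
        records, {structure.pdb_id: structure}, seq_provider, struct_provider
    )
    truth = make_synthetic_ddg(
        dataset.X.to_numpy(),
        config.informative_dims,
        noise_sd=config.noise_sd,
        noise_to_signal=config.noise_to_signal,
        seed=config.seed,
    )
    records_with_ddg = attach_targets(dataset.records, truth.targets)
    dataset = FeaturizedDataset(
        X=dataset.X, y=truth.targets.copy(), records=records_with_ddg, skipped=dataset.skipped
    )
    return SyntheticFixture(
        config=config,
        pdb_text=pdb_text,
        partner_spec=partner_spec,
        structure=structure,
        records=records_with_ddg,
        dataset=dataset,
        truth=truth,
        seq_provider=seq_provider,
        struct_provider=struct_provider,
    )


def write_fixture(directory: str | Path, fixture: SyntheticFixture) -> dict[str, Path]:
    """Emit complex.pdb, mutations.csv (in-house dialect) and truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "pdb": directory / "complex.pdb",
        "mutations": directory / "mutations.csv",
        "truth": directory / "truth.json",
    }
    paths["pdb"].write_text(fixture.pdb_text)
    write_mutation_table(fixture.records, paths["mutations"])
    truth = fixture.truth
    paths["truth"].write_text(json.dumps({
        "seed": truth.seed,
        "signal_sd": truth.signal_sd,
        "noise_sd": truth.noise_sd,
        "informative_idx": truth.informative_idx.tolist(),
        "weights_nonzero": {
            str(int(i)): float(truth.weights[i]) for i in truth.informative_idx
        },
    }, indent=2))
    return paths
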