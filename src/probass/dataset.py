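"""Mutation tables, complex structures and interface geometry.

The experimental unit is one measured binding free-energy change
(ΔΔG_bind, kcal/mol) for one or two point substitutions in a two-partner
protein complex.  This module parses the two tabular dialects such
measurements arrive in, merges overlapping sources, loads complex
structures from PDB files, applies substitutions to chain sequences and
finds binding-interface positions by Cα–Cα proximity.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: Standard 20-letter amino-acid alphabet (one-letter codes).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA20 = frozenset(AA_ORDER)

_STANDARD_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
#: Common modified residues mapped to their parent standard residue.
_MODIFIED_3TO1 = {
    "MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y",
    "CSO": "C", "HYP": "P", "SEC": "C", "PYL": "K", "MLY": "K",
}
THREE_TO_ONE = {**_STANDARD_3TO1, **_MODIFIED_3TO1}
ONE_TO_THREE = {v: k for k, v in _STANDARD_3TO1.items()}

SOURCES = ("inhouse", "skempi")
DIALECTS = ("skempi_like", "inhouse_like")


class TableParseError(ValueError):
    """A mutation table could not be read at all."""


class StructureError(ValueError):
    """A complex structure is missing required chains or coordinates."""


class WtMismatchError(ValueError):
    """The residue found at a mutation site differs from the declared wild type."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationSpec:
    """One point substitution: ``wt_aa`` at ``position`` of ``chain_id`` → ``mut_aa``.

    ``position`` is the author-assigned residue number, kept as a string so
    insertion codes ("100A") ride along untouched; no arithmetic is ever done
    on positions.
    """

    chain_id: str
    position: str
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", str(self.position))
        object.__setattr__(self, "wt_aa", self.wt_aa.upper())
        object.__setattr__(self, "mut_aa", self.mut_aa.upper())
        if len(self.chain_id) != 1:
            raise ValueError(f"chain_id must be a single character, got {self.chain_id!r}")
        for aa, role in ((self.wt_aa, "wt_aa"), (self.mut_aa, "mut_aa")):
            if aa not in AA20:
                raise ValueError(f"{role} {aa!r} is not a standard amino acid")
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"wild-type and mutant residues are identical "
                f"({self.wt_aa}{self.chain_id}{self.position}{self.mut_aa})"
            )

    @property
    def site(self) -> tuple[str, str]:
        return (self.chain_id, self.position)

    def token(self) -> str:
        """Compact token with the chain letter embedded, e.g. ``KI15A``."""
        return f"{self.wt_aa}{self.chain_id}{self.position}{self.mut_aa}"

    def reverse(self) -> "MutationSpec":
        return MutationSpec(self.chain_id, self.position, self.mut_aa, self.wt_aa)


@dataclass(frozen=True)
class MutationRecord:
    """One experimental measurement: 1–2 substitutions and their ΔΔG_bind.

    ``ddg_exp`` is None while a synthetic record is awaiting target
    generation; it must be finite whenever present.  ``ddg_error`` is the
    per-measurement standard deviation used by the noise-ceiling simulation.
    """

    pdb_id: str
    mutations: tuple[MutationSpec, ...]
    ddg_exp: float | None
    ddg_error: float | None = None
    source: str = "inhouse"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pdb_id", self.pdb_id.upper())
        object.__setattr__(self, "mutations", tuple(self.mutations))
        if not 1 <= len(self.mutations) <= 2:
            raise ValueError(f"records carry 1 or 2 mutations, got {len(self.mutations)}")
        sites = [m.site for m in self.mutations]
        if len(set(sites)) != len(sites):
            raise ValueError(f"mutations share a site: {sites}")
        if self.ddg_exp is not None and not math.isfinite(self.ddg_exp):
            raise ValueError(f"ddg_exp must be finite, got {self.ddg_exp}")
        if self.ddg_error is not None and (not math.isfinite(self.ddg_error) or self.ddg_error < 0):
            raise ValueError(f"ddg_error must be a finite non-negative value, got {self.ddg_error}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")

    @property
    def key(self) -> tuple[str, frozenset]:
        """Identity used for duplicate resolution: complex + mutation multiset."""
        return (self.pdb_id, frozenset(m.token() for m in self.mutations))

    @property
    def is_double(self) -> bool:
        return len(self.mutations) == 2

    def mutation_string(self) -> str:
        return ",".join(m.token() for m in self.mutations)


@dataclass(frozen=True)
class ChainSequence:
    """One chain's one-letter sequence plus its author residue numbering."""

    chain_id: str
    sequence: str
    numbering: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "numbering", tuple(str(p) for p in self.numbering))
        if len(self.sequence) != len(self.numbering):
            raise ValueError(
                f"chain {self.chain_id}: sequence length {len(self.sequence)} "
                f"!= numbering length {len(self.numbering)}"
            )
        if len(set(self.numbering)) != len(self.numbering):
            raise ValueError(f"chain {self.chain_id}: duplicate residue numbers")

    def index_of(self, position: str | int) -> int:
        position = str(position)
        try:
            return self.numbering.index(position)
        except ValueError:
            raise KeyError(
                f"position {position} not present in chain {self.chain_id}"
            ) from None

    def residue_at(self, position: str | int) -> str:
        return self.sequence[self.index_of(position)]

    def __len__(self) -> int:
        return len(self.sequence)


def apply_mutation(chain: ChainSequence, spec: MutationSpec) -> ChainSequence:
    """Return a copy of ``chain`` with ``spec`` applied at its author position.

    Raises :class:`KeyError` if the position is absent and
    :class:`WtMismatchError` if the residue found there is not ``spec.wt_aa``
    (such records are rejected upstream, with a logged count).
    """
    if spec.chain_id != chain.chain_id:
        raise ValueError(f"mutation targets chain {spec.chain_id}, sequence is chain {chain.chain_id}")
    idx = chain.index_of(spec.position)
    found = chain.sequence[idx]
    if found != spec.wt_aa:
        raise WtMismatchError(
            f"chain {chain.chain_id} position {spec.position} holds {found}, "
            f"mutation declares wild type {spec.wt_aa}"
        )
    mutated = chain.sequence[:idx] + spec.mut_aa + chain.sequence[idx + 1:]
    return replace(chain, sequence=mutated)


@dataclass(frozen=True)
class ComplexStructure:
    """A two-partner complex: chain sequences plus backbone coordinates.

    ``backbone[chain_id]`` is an (L, 3, 3) array of N, Cα, C coordinates in Å
    aligned index-for-index with that chain's sequence; atoms that were not
    resolved are NaN except Cα, which is guaranteed (residues without a Cα are
    dropped at load time so sequence and coordinates stay aligned).
    """

    pdb_id: str
    partner_a: tuple[ChainSequence, ...]
    partner_b: tuple[ChainSequence, ...]
    backbone: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pdb_id", self.pdb_id.upper())
        object.__setattr__(self, "partner_a", tuple(self.partner_a))
        object.__setattr__(self, "partner_b", tuple(self.partner_b))
        ids_a = {c.chain_id for c in self.partner_a}
        ids_b = {c.chain_id for c in self.partner_b}
        if not ids_a or not ids_b:
            raise StructureError("both binding partners need at least one chain")
        if ids_a & ids_b:
            raise StructureError(f"partner chain sets overlap: {ids_a & ids_b}")
        for chain in self.chains:
            coords = self.backbone.get(chain.chain_id)
            if coords is None or coords.shape != (len(chain), 3, 3):
                raise StructureError(
                    f"chain {chain.chain_id}: backbone array missing or misaligned"
                )
            if np.isnan(coords[:, 1, :]).any():
                raise StructureError(f"chain {chain.chain_id}: unresolved Cα coordinates")

    @property
    def chains(self) -> tuple[ChainSequence, ...]:
        return self.partner_a + self.partner_b

    def chain(self, chain_id: str) -> ChainSequence:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id} in complex {self.pdb_id}")

    @property
    def residue_index(self) -> tuple[tuple[str, str], ...]:
        """(chain_id, position) pairs in partner order — the embedding row order."""
        return tuple(
            (c.chain_id, pos) for c in self.chains for pos in c.numbering
        )

    def ca_coordinates(self, chains: Iterable[ChainSequence]) -> tuple[np.ndarray, list[tuple[str, str]]]:
        coords, labels = [], []
        for c in chains:
            coords.append(self.backbone[c.chain_id][:, 1, :])
            labels.extend((c.chain_id, pos) for pos in c.numbering)
        return np.concatenate(coords, axis=0), labels

    def swapped(self) -> "ComplexStructure":
        """The same complex with partner roles exchanged."""
        return replace(self, partner_a=self.partner_b, partner_b=self.partner_a)


# ---------------------------------------------------------------------------
# mutation-table parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rejection:
    path: str
    line: int
    reason: str


@dataclass
class ParseResult(Sequence):
    """Accepted records plus row-level rejections; behaves as the record list."""

    records: list[MutationRecord]
    rejections: list[Rejection] = field(default_factory=list)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, item):
        return self.records[item]


_TOKEN_RE = re.compile(r"^([A-Za-z])([A-Za-z]?)(\d+[A-Za-z]?)([A-Za-z])$")


def parse_mutation_token(token: str, default_chain: str | None = None) -> MutationSpec:
    """Parse ``K15A`` (chain supplied separately) or ``KI15A`` (chain embedded).

    The position may carry a single-letter insertion code; when both an
    insertion code and the mutant letter could absorb a trailing letter the
    longer position wins (greedy), matching the SKEMPI convention.
    """
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise ValueError(f"unparseable mutation token {token!r}")
    wt, chain, pos, mut = m.groups()
    if not chain:
        if default_chain is None:
            raise ValueError(f"token {token!r} carries no chain and none was supplied")
        chain = default_chain
    return MutationSpec(chain_id=chain, position=pos, wt_aa=wt, mut_aa=mut)


def _row_to_record(row: dict, dialect: str) -> MutationRecord:
    get = {k.lower().strip().lstrip("#"): v for k, v in row.items() if k}

    def pick(*names: str, required: bool = True) -> str | None:
        for n in names:
            v = get.get(n)
            if v is not None and str(v).strip() != "":
                return str(v).strip()
        if required:
            raise ValueError(f"missing column (one of {names})")
        return None

    if dialect == "skempi_like":
        pdb_field = pick("pdb", "pdb_id")
        pdb_id = pdb_field.split("_")[0]
        mut_field = pick("mutation(s)", "mutations", "mutation")
        specs = [parse_mutation_token(t) for t in mut_field.split(",") if t.strip()]
        ddg = float(pick("ddg", "ddg_exp"))
        err = pick("ddg_err", "ddg_error", required=False)
        source = "skempi"
    elif dialect == "inhouse_like":
        pdb_id = pick("pdb_id", "pdb")
        chain = pick("chain", required=False)
        mut_field = pick("mutation", "mutations")
        specs = [
            parse_mutation_token(t, default_chain=chain)
            for t in mut_field.split(",")
            if t.strip()
        ]
        ddg = float(pick("ddg_exp", "ddg"))
        err = pick("ddg_error", "ddg_err", required=False)
        source = pick("source", required=False) or "inhouse"
    else:
        raise TableParseError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    return MutationRecord(
        pdb_id=pdb_id,
        mutations=tuple(specs),
        ddg_exp=ddg,
        ddg_error=float(err) if err is not None else None,
        source=source,
    )


def parse_mutation_table(path: str | Path, dialect: str) -> ParseResult:
    """Parse a mutation table in one of the two declared dialects.

    ``skempi_like`` is semicolon-separated with chain letters embedded in the
    mutation tokens; ``inhouse_like`` is a plain CSV with an optional
    ``chain`` column applying to bare tokens.  Dialects are declared, never
    sniffed.  Every row yields one record or a logged, counted rejection;
    an unreadable file raises :class:`TableParseError`.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise TableParseError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    delimiter = ";" if dialect == "skempi_like" else ","
    records: list[MutationRecord] = []
    rejections: list[Rejection] = []
    try:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delimiter)
            if reader.fieldnames is None:
                raise TableParseError(f"{path}: empty table")
            for lineno, row in enumerate(reader, start=2):
                try:
                    records.append(_row_to_record(row, dialect))
                except (ValueError, KeyError) as exc:
                    rej = Rejection(str(path), lineno, str(exc))
                    rejections.append(rej)
                    logger.warning("rejected %s:%d: %s", rej.path, rej.line, rej.reason)
    except OSError as exc:
        raise TableParseError(f"cannot read {path}: {exc}") from exc
    logger.info(
        "%s: parsed %d records, rejected %d rows", path, len(records), len(rejections)
    )
    return ParseResult(records, rejections)


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write the normalized table; re-parseable with the ``inhouse_like`` dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pdb_id", "mutations", "ddg_exp", "ddg_error", "source"])
        for rec in records:
            writer.writerow([
                rec.pdb_id,
                rec.mutation_string(),
                "" if rec.ddg_exp is None else repr(rec.ddg_exp),
                "" if rec.ddg_error is None else repr(rec.ddg_error),
                rec.source,
            ])


def _collapse_within_source(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    groups: dict[tuple, list[MutationRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        if rec.key not in groups:
            order.append(rec.key)
        groups.setdefault(rec.key, []).append(rec)
    out = []
    for key in order:
        group = groups[key]
        first = group[0]
        if len(group) == 1:
            out.append(first)
            continue
        ddg = float(np.mean([r.ddg_exp for r in group]))
        errs = [r.ddg_error for r in group if r.ddg_error is not None]
        err = float(np.mean(errs)) if errs else None
        out.append(replace(first, ddg_exp=ddg, ddg_error=err))
    return out


def resolve_duplicates(
    inhouse: Iterable[MutationRecord], skempi: Iterable[MutationRecord]
) -> list[MutationRecord]:
    """Merge the two sources.

    Exact duplicates within one source collapse to a single record carrying
    the mean ΔΔG; whenever the same (complex, mutation set) appears in both
    sources only the in-house measurement survives.  Idempotent.
    """
    inhouse = _collapse_within_source(inhouse)
    skempi = _collapse_within_source(skempi)
    inhouse_keys = {rec.key for rec in inhouse}
    merged = list(inhouse)
    dropped = 0
    for rec in skempi:
        if rec.key in inhouse_keys:
            dropped += 1
            continue
        merged.append(rec)
    if dropped:
        logger.info("duplicate resolution: %d database records superseded by in-house data", dropped)
    return merged


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def load_complex(
    pdb_path: str | Path,
    partner_spec: tuple[Iterable[str], Iterable[str]],
    pdb_id: str | None = None,
) -> ComplexStructure:
    """Load a two-partner complex from a PDB file.

    ``pdb_id`` defaults to the file stem.

    Sequences are derived from residues with a resolved Cα; modified residues
    with a known parent (MSE and friends) are mapped to the parent letter,
    other unknown polymer residues are skipped with a logged warning; hetero
    compounds and waters are ignored.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    pdb_path = Path(pdb_path)
    group_a = [str(c) for c in partner_spec[0]]
    group_b = [str(c) for c in partner_spec[1]]
    if not group_a or not group_b:
        raise StructureError("both partner groups must name at least one chain")

    pdb_file = pdbio.PDBFile.read(str(pdb_path))
    atoms = pdb_file.get_structure(model=1)
    pdb_id = pdb_id or pdb_path.stem

    chains: dict[str, ChainSequence] = {}
    backbone: dict[str, np.ndarray] = {}
    n_skipped_unknown = 0
    n_missing_ca = 0
    for chain_id in group_a + group_b:
        chain_atoms = atoms[atoms.chain_id == chain_id]
        if chain_atoms.array_length() == 0:
            raise StructureError(f"{pdb_path}: chain {chain_id} not present")
        letters: list[str] = []
        numbering: list[str] = []
        coords: list[np.ndarray] = []
        for res in struc.residue_iter(chain_atoms):
            name = res.res_name[0]
            if name == "HOH" or (res.hetero[0] and name not in THREE_TO_ONE):
                continue  # water / ligand
            letter = THREE_TO_ONE.get(name)
            if letter is None:
                n_skipped_unknown += 1
                logger.warning(
                    "%s chain %s residue %s%s: unknown residue %s skipped",
                    pdb_id, chain_id, res.res_id[0], res.ins_code[0].strip(), name,
                )
                continue
            bb = np.full((3, 3), np.nan)
            for i, atom_name in enumerate(("N", "CA", "C")):
                sel = res[res.atom_name == atom_name]
                if sel.array_length():
                    bb[i] = sel.coord[0]
            if np.isnan(bb[1]).any():
                n_missing_ca += 1
                continue  # no Cα: excluded from sequence and embedding input
            letters.append(letter)
            numbering.append(f"{res.res_id[0]}{res.ins_code[0].strip()}")
            coords.append(bb)
        if not letters:
            raise StructureError(f"{pdb_path}: chain {chain_id} has no resolved residues")
        chains[chain_id] = ChainSequence(chain_id, "".join(letters), tuple(numbering))
        backbone[chain_id] = np.stack(coords)
    if n_missing_ca:
        logger.info("%s: %d residues without Cα excluded", pdb_id, n_missing_ca)
    if n_skipped_unknown:
        logger.info("%s: %d unknown residues skipped", pdb_id, n_skipped_unknown)

    return ComplexStructure(
        pdb_id=pdb_id,
        partner_a=tuple(chains[c] for c in group_a),
        partner_b=tuple(chains[c] for c in group_b),
        backbone=backbone,
    )


def interface_positions(
    structure: ComplexStructure, cutoff: float = 4.0
) -> set[tuple[str, str]]:
    """Positions whose Cα lies within ``cutoff`` Å (inclusive) of the opposite partner.

    The 4 Å Cα–Cα default is deliberately strict; pass a larger cutoff to
    relax it.  Symmetric in the two partners; monotone non-decreasing in
    ``cutoff``.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    coords_a, labels_a = structure.ca_coordinates(structure.partner_a)
    coords_b, labels_b = structure.ca_coordinates(structure.partner_b)
    if coords_a.size == 0 or coords_b.size == 0:
        raise StructureError("a partner has no Cα coordinates")
    dist = cdist(coords_a, coords_b)
    close = dist <= cutoff
    hits: set[tuple[str, str]] = set()
    ia, ib = np.nonzero(close)
    hits.update(labels_a[i] for i in ia)
    hits.update(labels_b[j] for j in ib)
    return hits
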