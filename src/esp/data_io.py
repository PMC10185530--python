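"""Canonical data model and file I/O for enzymes, molecules and labeled pairs.

The package operates on three tables: enzymes (id + amino-acid sequence),
molecules (id + structure given as SMILES, InChI or MDL Molfile text), and
pairs (enzyme_id x molecule_id with a binary label and an evidence tier).
Readers validate on ingestion; a :class:`Dataset` bundles the three tables
and enforces referential integrity.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "EnzymeRecord",
    "MoleculeRecord",
    "PairRecord",
    "Dataset",
    "IntegrityError",
    "read_enzymes",
    "read_molecules",
    "read_pairs",
    "write_pairs",
    "write_enzymes",
    "write_molecules",
]

#: residues accepted in enzyme sequences: the 20 standard amino acids plus
#: ambiguity codes B/Z, unknown X and selenocysteine U.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" "XBZU")

VALID_EVIDENCE = ("experimental", "phylogenetic", "sampled")

#: default blocklist applied by ``drop_small_inorganics``: ubiquitous tiny
#: co-substrates whose fingerprints are degenerate (water, oxygen, common ions).
SMALL_INORGANIC_SMILES = frozenset(
    ["O", "[OH2]", "O=O", "[O][O]", "[H+]", "[Na+]", "[K+]", "[Cl-]", "[Ca+2]",
     "[Mg+2]", "[Fe+2]", "[Fe+3]", "[Zn+2]", "[Mn+2]", "[NH4+]"]
)


class IntegrityError(ValueError):
    """Raised when a table violates uniqueness or referential integrity."""


@dataclass(frozen=True)
class EnzymeRecord:
    """An enzyme: opaque identifier plus amino-acid sequence."""

    enzyme_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"enzyme {self.enzyme_id!r}: empty sequence")
        bad = set(self.sequence.upper()) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"enzyme {self.enzyme_id!r}: invalid residues {sorted(bad)}"
            )


@dataclass
class MoleculeRecord:
    """A small molecule: identifier, raw structure text and its source format.

    ``parsed`` holds the RDKit Mol once :mod:`esp.molecule_features` has seen
    the record; readers leave it None.
    """

    molecule_id: str
    structure_source: str  # one of smiles / inchi / molfile
    structure_text: str
    parsed: object | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        src = self.structure_source.lower()
        if src not in ("smiles", "inchi", "molfile"):
            raise ValueError(
                f"molecule {self.molecule_id!r}: unknown structure source "
                f"{self.structure_source!r}"
            )
        object.__setattr__(self, "structure_source", src)


@dataclass(frozen=True)
class PairRecord:
    """A labeled enzyme-molecule pair.

    label 1 = substrate (positive), 0 = non-substrate. ``evidence`` records
    how the label arose: experimental, phylogenetically inferred, or sampled
    (negatives generated by the similarity-windowed sampler, always label 0).
    """

    enzyme_id: str
    molecule_id: str
    label: int
    evidence: str = "experimental"
    origin: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"pair label must be 0 or 1, got {self.label!r}")
        if self.evidence not in VALID_EVIDENCE:
            raise ValueError(
                f"evidence must be one of {VALID_EVIDENCE}, got {self.evidence!r}"
            )
        if self.evidence == "sampled" and self.label != 0:
            raise ValueError("sampled pairs must carry label 0")


@dataclass
class Dataset:
    """Bundle of the three tables with referential integrity enforced."""

    enzymes: list[EnzymeRecord]
    molecules: list[MoleculeRecord]
    pairs: list[PairRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_unique([e.enzyme_id for e in self.enzymes], "enzyme_id")
        _check_unique([m.molecule_id for m in self.molecules], "molecule_id")
        eids = {e.enzyme_id for e in self.enzymes}
        mids = {m.molecule_id for m in self.molecules}
        for p in self.pairs:
            if p.enzyme_id not in eids:
                raise IntegrityError(f"pair references unknown enzyme {p.enzyme_id!r}")
            if p.molecule_id not in mids:
                raise IntegrityError(
                    f"pair references unknown molecule {p.molecule_id!r}"
                )
        triples = [(p.enzyme_id, p.molecule_id, p.label) for p in self.pairs]
        _check_unique(triples, "(enzyme_id, molecule_id, label)")

    @property
    def enzyme_index(self) -> dict[str, EnzymeRecord]:
        return {e.enzyme_id: e for e in self.enzymes}

    @property
    def molecule_index(self) -> dict[str, MoleculeRecord]:
        return {m.molecule_id: m for m in self.molecules}

    def positives(self) -> list[PairRecord]:
        return [p for p in self.pairs if p.label == 1]


def _check_unique(keys: Sequence, what: str) -> None:
    dupes = [k for k, n in collections.Counter(keys).items() if n > 1]
    if dupes:
        raise IntegrityError(f"duplicate {what}: {dupes[:10]}")


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """CSV by default; pass sep='\\t' for tab-separated input."""
    return pd.read_csv(path, sep=sep or ",", dtype=str, keep_default_na=False)


def read_enzymes(path: str | Path, format: str = "fasta", sep: str | None = None
                 ) -> list[EnzymeRecord]:
    """Read enzymes from FASTA or a tabular file with columns enzyme_id, sequence.

    FASTA ids follow the usual convention: the header token up to the first
    whitespace is the enzyme_id.
    """
    path = Path(path)
    if format == "fasta":
        records = [
            EnzymeRecord(enzyme_id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    elif format == "tabular":
        df = _read_table(path, sep)
        _require_columns(df, ["enzyme_id", "sequence"], path)
        records = [
            EnzymeRecord(enzyme_id=r.enzyme_id, sequence=r.sequence.upper())
            for r in df.itertuples()
        ]
    else:
        raise ValueError(f"unknown enzyme format {format!r}")
    _check_unique([e.enzyme_id for e in records], "enzyme_id")
    return records


def write_enzymes(path: str | Path, enzymes: Iterable[EnzymeRecord]) -> None:
    with open(path, "w") as fh:
        for e in enzymes:
            fh.write(f">{e.enzyme_id}\n{e.sequence}\n")


def read_molecules(path: str | Path, sep: str | None = None,
                   drop_small_inorganics: bool = False
                   ) -> tuple[list[MoleculeRecord], list[tuple[str, str]]]:
    """Read molecules from a table (molecule_id, structure_source, structure_text).

    Every row is parse-checked with RDKit. Returns ``(accepted, rejected)``
    where rejected is a list of (molecule_id, reason); the run continues past
    unparseable rows so a bad structure never aborts ingestion.

    ``drop_small_inorganics`` applies an explicit blocklist of water, oxygen
    and common ions (their fingerprints are degenerate); it is off by default
    because exclusion lists are dataset-specific.
    """
    from esp.molecule_features import parse_structure  # deferred: rdkit import

    df = _read_table(path, sep)
    _require_columns(df, ["molecule_id", "structure_source", "structure_text"], path)
    accepted: list[MoleculeRecord] = []
    rejected: list[tuple[str, str]] = []
    for r in df.itertuples():
        try:
            rec = MoleculeRecord(r.molecule_id, r.structure_source, r.structure_text)
            mol = parse_structure(rec)
        except Exception as exc:  # per-row failure, summarised for the caller
            rejected.append((r.molecule_id, str(exc)))
            continue
        if drop_small_inorganics and _is_small_inorganic(mol):
            rejected.append((r.molecule_id, "blocklisted small inorganic"))
            continue
        rec.parsed = mol
        accepted.append(rec)
    _check_unique([m.molecule_id for m in accepted], "molecule_id")
    return accepted, rejected


def _is_small_inorganic(mol) -> bool:
    from rdkit import Chem

    return Chem.MolToSmiles(mol) in {
        Chem.CanonSmiles(s) for s in SMALL_INORGANIC_SMILES
    }


PAIR_COLUMNS = ["enzyme_id", "molecule_id", "label", "evidence", "origin"]


def read_pairs(path: str | Path, sep: str | None = None) -> list[PairRecord]:
    df = _read_table(path, sep)
    _require_columns(df, ["enzyme_id", "molecule_id", "label"], path)
    pairs = []
    for r in df.itertuples():
        pairs.append(
            PairRecord(
                enzyme_id=r.enzyme_id,
                molecule_id=r.molecule_id,
                label=int(r.label),
                evidence=getattr(r, "evidence", "experimental") or "experimental",
                origin=getattr(r, "origin", "") or "",
            )
        )
    return pairs


def write_pairs(path: str | Path, pairs: Iterable[PairRecord],
                sep: str = ",") -> None:
    df = pd.DataFrame(
        [(p.enzyme_id, p.molecule_id, p.label, p.evidence, p.origin) for p in pairs],
        columns=PAIR_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


def write_molecules(path: str | Path, molecules: Iterable[MoleculeRecord],
                    sep: str = ",") -> None:
    df = pd.DataFrame(
        [(m.molecule_id, m.structure_source, m.structure_text) for m in molecules],
        columns=["molecule_id", "structure_source", "structure_text"],
    )
    df.to_csv(path, sep=sep, index=False)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
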