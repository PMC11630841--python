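"""Read and write AlphaFold-style structure models and domain-annotation tables.

AlphaFold-family predictors store the per-residue confidence score (plDDT, on a
0-100 scale) in the B-factor / temperature-factor column of the deposited
coordinate file.  This module reads that convention back into a lightweight
:class:`StructureModel`, writes minimal Calpha-trace models that round-trip
through the same reader, and computes whole-protein and domain-restricted mean
plDDT values.

Only single-chain models are supported: a rescue pipeline that silently picked
one chain of a complex would mis-assign confidences, so multi-chain input is an
explicit error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    MalformedModelError,
    SchemaError,
    TableParseError,
    UnsupportedInputError,
    ValidationError,
)

__all__ = [
    "StructureModel",
    "DomainAnnotation",
    "read_model",
    "read_models",
    "write_model",
    "mean_plddt",
    "read_domain_table",
    "write_domain_table",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


@dataclass
class StructureModel:
    """One protein's structure model with per-residue confidence.

    Parameters
    ----------
    protein_id : str
        Accession of the protein (e.g. a UniProtKB accession).
    sequence : str
        One-letter amino-acid sequence of length L; nonstandard residues are
        represented as ``X`` and keep their plDDT entry so that domain spans
        stay in register.
    plddt : numpy.ndarray
        Length-L vector of per-residue plDDT values in [0, 100].
    ca_coords : numpy.ndarray, optional
        (L, 3) array of Calpha coordinates in Angstrom.
    source_path : pathlib.Path, optional
        File the model was read from, if any.
    """

    protein_id: str
    sequence: str
    plddt: np.ndarray
    ca_coords: np.ndarray | None = None
    source_path: Path | None = None

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        if len(self.plddt) != len(self.sequence):
            raise ValidationError(
                f"{self.protein_id}: plddt length {len(self.plddt)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.plddt.size and (self.plddt.min() < 0 or self.plddt.max() > 100):
            raise ValidationError(
                f"{self.protein_id}: plDDT values must lie in [0, 100]"
            )
        if self.ca_coords is not None:
            self.ca_coords = np.asarray(self.ca_coords, dtype=float)
            if self.ca_coords.shape != (len(self.sequence), 3):
                raise ValidationError(
                    f"{self.protein_id}: ca_coords shape {self.ca_coords.shape} "
                    f"does not match sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_plddt(self) -> float:
        return float(np.mean(self.plddt))


@dataclass
class DomainAnnotation:
    """Family membership of a protein with its domain extent.

    ``start``/``end`` are 1-based inclusive residue indices (Pfam convention).
    ``is_fragment`` marks database entries missing regions outside the domain
    of interest; the cohort selector de-prioritizes them.
    """

    protein_id: str
    family_id: str
    start: int
    end: int
    is_fragment: bool = False
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.protein_id}: invalid domain span {self.start}..{self.end}"
            )
        if self.sequence is not None and self.end > len(self.sequence):
            raise ValidationError(
                f"{self.protein_id}: domain end {self.end} exceeds sequence "
                f"length {len(self.sequence)}"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _structure_from_file(path: Path, format: str) -> gemmi.Structure:
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(st) == 0 or all(len(model) == 0 for model in st):
        raise FormatError(f"{path}: no chains found")
    return st


def read_model(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a single-chain model; plDDT is taken from the B-factor column.

    The representative atom per residue is the Calpha if present, else the
    first atom.  Residues are ordered by residue number.  The protein id is
    the file stem.
    """
    path = Path(path)
    if format not in ("pdb", "mmcif", "auto"):
        raise ValueError(f"unknown format {format!r}")
    st = _structure_from_file(path, format)
    model = st[0]
    chains = [ch for ch in model if len(ch) > 0]
    if len(chains) != 1:
        names = ", ".join(ch.name for ch in chains)
        raise UnsupportedInputError(
            f"{path}: expected a single chain, found {len(chains)} ({names})"
        )
    chain = chains[0]
    residues = sorted(chain, key=lambda r: r.seqid.num)
    seq_chars: list[str] = []
    plddt: list[float] = []
    coords: list[tuple[float, float, float]] = []
    have_all_ca = True
    for res in residues:
        if len(res) == 0:
            raise MalformedModelError(
                f"{path}: residue {res.name} {res.seqid.num} has no atoms"
            )
        ca = res.find_atom("CA", "*")
        rep = ca if ca is not None else res[0]
        seq_chars.append(_THREE_TO_ONE.get(res.name.upper(), "X"))
        plddt.append(rep.b_iso)
        if ca is not None:
            coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
        else:
            have_all_ca = False
    arr = np.asarray(plddt, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 100):
        raise ValidationError(
            f"{path}: B-factor column holds values outside [0, 100]; "
            "not a plDDT-annotated model"
        )
    return StructureModel(
        protein_id=path.stem,
        sequence="".join(seq_chars),
        plddt=arr,
        ca_coords=np.asarray(coords) if have_all_ca and coords else None,
        source_path=path,
    )


def read_models(path: str | Path, format: str = "auto") -> list[StructureModel]:
    """Read one model file, or every ``*.pdb``/``*.cif`` file in a directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".pdb", ".cif")
        )
        return [read_model(p, format) for p in files]
    return [read_model(path, format)]


def write_model(
    model: StructureModel, path: str | Path, format: str = "pdb"
) -> Path:
    """Write a minimal Calpha-trace model; plDDT goes into the B-factor column.

    The written dialect is one CA atom per residue, occupancy 1.00, B-factor
    with two decimals -- sufficient for template hand-off to a predictor and
    re-readable by :func:`read_model`.
    """
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    if model.ca_coords is None:
        raise ValidationError(
            f"{model.protein_id}: cannot write a model without ca_coords"
        )
    if model.plddt.size and (model.plddt.min() < 0 or model.plddt.max() > 100):
        raise ValidationError(f"{model.protein_id}: plDDT outside [0, 100]")
    path = Path(path)

    st = gemmi.Structure()
    st.name = model.protein_id
    gm = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (aa, b, xyz) in enumerate(
        zip(model.sequence, model.plddt, model.ca_coords), start=1
    ):
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(aa, "UNK")
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        atom.b_iso = round(float(b), 2)
        res.add_atom(atom)
        chain.add_residue(res)
    gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


def mean_plddt(
    model: StructureModel, span: tuple[int, int] | None = None
) -> float:
    """Arithmetic mean plDDT over ``span`` (1-based inclusive) or the whole protein."""
    if span is None:
        return float(np.mean(model.plddt))
    start, end = span
    if not (1 <= start <= end <= len(model)):
        raise IndexError(
            f"span {start}..{end} out of bounds for length {len(model)}"
        )
    return float(np.mean(model.plddt[start - 1 : end]))


_REQUIRED_COLUMNS = ("protein_id", "family_id", "start", "end", "is_fragment")
_TRUE_STRINGS = {"true", "1", "yes", "t"}
_FALSE_STRINGS = {"false", "0", "no", "f"}


def _parse_bool(value: object, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise TableParseError(f"row {row}: cannot parse is_fragment value {value!r}")


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a TSV of domain annotations.

    Required header columns: protein_id, family_id, start, end, is_fragment;
    an optional ``sequence`` column carries the full protein sequence.  Row
    numbers in errors are 1-based data rows (header excluded).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    has_seq = "sequence" in df.columns
    annotations: list[DomainAnnotation] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start = int(getattr(row, "start"))
            end = int(getattr(row, "end"))
        except (TypeError, ValueError) as exc:
            raise TableParseError(
                f"row {idx}: non-integer domain span "
                f"({getattr(row, 'start')!r}, {getattr(row, 'end')!r})"
            ) from exc
        seq = getattr(row, "sequence") if has_seq else None
        if seq is not None and (not isinstance(seq, str) or seq == ""):
            seq = None
        try:
            annotations.append(
                DomainAnnotation(
                    protein_id=str(getattr(row, "protein_id")),
                    family_id=str(getattr(row, "family_id")),
                    start=start,
                    end=end,
                    is_fragment=_parse_bool(getattr(row, "is_fragment"), idx),
                    sequence=seq,
                )
            )
        except ValidationError as exc:
            raise TableParseError(f"row {idx}: {exc}") from exc
    return annotations


def write_domain_table(
    annotations: Iterable[DomainAnnotation], path: str | Path
) -> Path:
    """Write annotations as the TSV consumed by :func:`read_domain_table`."""
    rows = [
        {
            "protein_id": a.protein_id,
            "family_id": a.family_id,
            "start": a.start,
            "end": a.end,
            "is_fragment": a.is_fragment,
            "sequence": a.sequence if a.sequence is not None else "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)
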