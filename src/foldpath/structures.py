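"""Domain types and I/O for folding-pathway intermediates.

A folding pathway is a time-ordered series of 3D conformational states
(intermediates) a protein passes through on its way to the native
structure.  Experimentally, an intermediate may be deposited as several
distinct conformations, each covering a *deposited* sequence range of
which only a *modeled* sub-range has coordinates.  This module holds the
in-memory representation of those objects, multi-model PDB reading and
writing (Cα-centric), residue mapping between conformations that share a
protein, and the tabular manifest cataloguing studies/intermediates/
conformations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from biotite.structure import Atom, array as atom_array, stack
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "Conformation",
    "Pathway",
    "Manifest",
    "MANIFEST_COLUMNS",
    "read_structure",
    "write_structure",
    "map_common_residues",
    "read_manifest",
    "write_manifest",
]


def _three_to_one(res_name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(res_name.capitalize())
    except KeyError:
        return "X"


def _one_to_three(aa: str) -> str:
    try:
        return ProteinSequence.convert_letter_1to3(aa).upper()
    except KeyError:
        return "UNK"


@dataclass
class Residue:
    """One amino acid: author residue number, one-letter code, Cα position.

    ``atoms`` optionally carries further (atom name, coordinate) pairs for
    contact definitions that need more than the Cα trace.
    """

    seq_index: int
    aa: str
    ca: np.ndarray
    atoms: list[tuple[str, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.shape != (3,):
            raise ValueError("ca must be a 3-vector")
        if not np.all(np.isfinite(self.ca)):
            raise ValueError("ca coordinates must be finite")
        if self.seq_index < 1:
            raise ValueError("seq_index must be >= 1 (author numbering)")


@dataclass
class Conformation:
    """One 3D structural state of a (possibly partial) protein chain.

    ``deposited_range`` is the inclusive residue-number span reported for
    the entry; ``modeled_range`` the sub-span that actually has
    coordinates.  Residues are ordered by strictly increasing author
    residue number.
    """

    protein_id: str
    residues: list[Residue]
    intermediate_index: int = 0
    conformation_label: str = "a"
    deposited_range: tuple[int, int] | None = None
    modeled_range: tuple[int, int] | None = None
    is_native: bool = False

    def __post_init__(self) -> None:
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue seq_index must be strictly increasing")
        if self.modeled_range is None and idx:
            self.modeled_range = (idx[0], idx[-1])
        if self.deposited_range is None:
            self.deposited_range = self.modeled_range
        if idx and self.deposited_range is not None:
            lo, hi = self.deposited_range
            if idx[0] < lo or idx[-1] > hi:
                raise ValueError("residues fall outside deposited_range")
        if self.modeled_range is not None and self.deposited_range is not None:
            if (self.modeled_range[0] < self.deposited_range[0]
                    or self.modeled_range[1] > self.deposited_range[1]):
                raise ValueError("modeled_range must lie within deposited_range")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def seq_indices(self) -> np.ndarray:
        return np.array([r.seq_index for r in self.residues], dtype=int)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in residue order."""
        if not self.residues:
            return np.zeros((0, 3))
        return np.stack([r.ca for r in self.residues])

    def subset(self, positions: np.ndarray | list[int]) -> "Conformation":
        """New Conformation keeping the residues at the given list positions."""
        res = [self.residues[i] for i in positions]
        lo, hi = res[0].seq_index, res[-1].seq_index
        return replace(self, residues=res, deposited_range=(lo, hi),
                       modeled_range=(lo, hi))


@dataclass
class Pathway:
    """Time-ordered intermediates, each holding one or more conformations."""

    protein_id: str
    intermediates: list[tuple[int, list[Conformation]]]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.intermediates]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("intermediate time indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.intermediates)

    @property
    def times(self) -> list[int]:
        return [t for t, _ in self.intermediates]

    def single_conformations(self) -> list[Conformation]:
        """One conformation per intermediate; error if any holds several."""
        out = []
        for t, confs in self.intermediates:
            if len(confs) != 1:
                raise ValueError(
                    f"intermediate {t} holds {len(confs)} conformations; "
                    "select one before snapshot-based analyses"
                )
            out.append(confs[0])
        return out

    def validate_cotranslational(self) -> bool:
        """True if deposited ranges are nested prefixes (start fixed,
        end non-decreasing) and any native is last."""
        ranges = []
        for _, confs in self.intermediates:
            for c in confs:
                ranges.append((c.deposited_range, c.is_native))
        starts = {r[0] for r, _ in ranges}
        ends = [r[1] for r, _ in ranges]
        prefix_ok = len(starts) == 1 and all(b >= a for a, b in zip(ends, ends[1:]))
        max_t = self.intermediates[-1][0]
        native_ok = all(
            not c.is_native or t == max_t
            for t, confs in self.intermediates for c in confs
        )
        return prefix_ok and native_ok


# ---------------------------------------------------------------------------
# PDB I/O

def read_structure(
    path: str | Path,
    model_policy: str = "all",
    chain: str | None = None,
    protein_id: str | None = None,
) -> list[Conformation]:
    """Read a (multi-model) PDB file into one Conformation per model.

    Parameters
    ----------
    path:
        PDB file with ATOM records; MODEL/ENDMDL blocks optional.
    model_policy:
        ``"all"`` (one Conformation per model) or ``"first"``.
    chain:
        Chain id to keep; defaults to the first chain in the file.  This
        is how attached entities (ribosome, fusion partner) deposited in
        other chains are excluded from the nascent-chain analysis.
    """
    if model_policy not in {"all", "first"}:
        raise ValueError("model_policy must be 'all' or 'first'")
    path = Path(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no models found")
    if protein_id is None:
        protein_id = path.stem
    n_take = 1 if model_policy == "first" else n_models
    confs = []
    for m in range(1, n_take + 1):
        arr = pdb.get_structure(model=m, altloc="occupancy")
        arr = arr[~arr.hetero]
        if arr.array_length() == 0:
            raise ValueError(f"{path}: model {m} has no ATOM records")
        if np.any(arr.ins_code != ""):
            raise ValueError(f"{path}: insertion codes are not supported")
        sel_chain = chain if chain is not None else arr.chain_id[0]
        arr = arr[arr.chain_id == sel_chain]
        if arr.array_length() == 0:
            raise ValueError(f"{path}: chain {sel_chain!r} not found in model {m}")
        residues: list[Residue] = []
        for res_id in np.unique(arr.res_id):
            sub = arr[arr.res_id == res_id]
            ca_mask = sub.atom_name == "CA"
            if not np.any(ca_mask):
                logger.warning("%s model %d residue %d: no CA, dropped",
                               path.name, m, res_id)
                continue
            atoms = [(name, c.copy())
                     for name, c in zip(sub.atom_name, sub.coord)]
            residues.append(Residue(
                seq_index=int(res_id),
                aa=_three_to_one(str(sub.res_name[0])),
                ca=sub.coord[ca_mask][0].copy(),
                atoms=atoms,
            ))
        confs.append(Conformation(
            protein_id=protein_id,
            residues=residues,
            conformation_label=chr(ord("a") + m - 1) if n_take > 1 else "a",
        ))
    return confs


def write_structure(conformations: list[Conformation], path: str | Path) -> None:
    """Write conformations to PDB; multiple ones become MODEL/ENDMDL blocks.

    Cα-only output: downstream scoring is Cα-based and re-reading
    reproduces seq_index, one-letter code and coordinates to PDB
    precision (3 decimals).
    """
    if not conformations:
        raise ValueError("cannot write an empty conformation list")
    ids = {c.protein_id for c in conformations}
    if len(ids) > 1:
        raise ValueError(f"inconsistent protein_id values: {sorted(ids)}")
    arrays = []
    for conf in conformations:
        atoms = [
            Atom(r.ca, chain_id="A", res_id=r.seq_index,
                 res_name=_one_to_three(r.aa), atom_name="CA", element="C")
            for r in conf.residues
        ]
        arrays.append(atom_array(atoms))
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        keys = {tuple(a.res_id) for a in arrays}
        if len(keys) > 1:
            raise ValueError(
                "multi-model writes require identical residue sets across "
                "conformations (PDB MODEL blocks share one atom table)")
        pdb.set_structure(stack(arrays))
    pdb.write(str(path))


def map_common_residues(a: Conformation, b: Conformation) -> list[tuple[int, int]]:
    """Positions (into a, into b) of residues shared by author number.

    Mapping is by residue number, not list position, so partial chains
    with unmodeled gaps map correctly.  Ascending order; empty if the
    modeled ranges are disjoint.
    """
    if a.protein_id != b.protein_id:
        raise ValueError(
            f"cannot map residues across proteins {a.protein_id!r} vs {b.protein_id!r}"
        )
    pos_b = {r.seq_index: j for j, r in enumerate(b.residues)}
    return [(i, pos_b[r.seq_index]) for i, r in enumerate(a.residues)
            if r.seq_index in pos_b]


# ---------------------------------------------------------------------------
# Manifest

MANIFEST_COLUMNS = [
    "study", "protein_id", "intermediate_index", "conformation_label",
    "pdb_id", "deposited_start", "deposited_end", "modeled_start",
    "modeled_end", "is_native", "excluded", "exclusion_reason",
]

_RANGE_RE = re.compile(r"^\s*(\d+)\s*[-–—]\s*(\d+)\s*$")


def parse_range(text: str) -> tuple[int, int]:
    """Parse '1-27' (hyphen, en- or em-dash) into an inclusive pair."""
    m = _RANGE_RE.match(str(text))
    if not m:
        raise ValueError(f"unparseable residue range: {text!r}")
    lo, hi = int(m.group(1)), int(m.group(2))
    if hi < lo:
        raise ValueError(f"range end before start: {text!r}")
    return lo, hi


@dataclass
class Manifest:
    """Catalogue of studies / intermediates / conformations (the
    machine-readable twin of the co-translational data table)."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=MANIFEST_COLUMNS))

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        self.table = self.table[MANIFEST_COLUMNS].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        t = self.table
        key = t[["pdb_id", "conformation_label", "intermediate_index"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate manifest key {dup}")
        bad = t[(t["modeled_start"] < t["deposited_start"])
                | (t["modeled_end"] > t["deposited_end"])]
        if len(bad):
            raise ValueError(
                "modeled range outside deposited range for pdb_id(s): "
                f"{sorted(bad['pdb_id'].unique())}"
            )
        noreason = t[t["excluded"].astype(bool)
                     & (t["exclusion_reason"].fillna("").str.strip() == "")]
        if len(noreason):
            raise ValueError("excluded rows must carry an exclusion_reason")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_studies(self) -> int:
        return self.table["study"].nunique()

    @property
    def n_intermediates(self) -> int:
        return len(self.table[["study", "intermediate_index"]].drop_duplicates())

    @property
    def n_conformations(self) -> int:
        return len(self.table)


def read_manifest(path: str | Path) -> Manifest:
    """Read a manifest TSV; also accepts 'deposited_range'/'modeled_range'
    columns in '1-27' form (en-dash tolerated)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for prefix in ("deposited", "modeled"):
        if f"{prefix}_range" in df.columns:
            pairs = df[f"{prefix}_range"].map(parse_range)
            df[f"{prefix}_start"] = [p[0] for p in pairs]
            df[f"{prefix}_end"] = [p[1] for p in pairs]
            df = df.drop(columns=[f"{prefix}_range"])
    for col in ("intermediate_index", "deposited_start", "deposited_end",
                "modeled_start", "modeled_end"):
        df[col] = df[col].astype(int)
    for col in ("is_native", "excluded"):
        df[col] = df[col].str.strip().str.lower().isin({"1", "true", "yes"})
    if "exclusion_reason" not in df.columns:
        df["exclusion_reason"] = ""
    return Manifest(df)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)
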