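"""Readers and writers for the pipeline's standard on-disk formats.

Array-length and track tables are plain TSV, proteomes are FASTA
(Bio.SeqIO), lattices are PDB/mmCIF pseudo-atom models (gemmi; chain = PF
index, residue number = repeat index), and micrographs are 32-bit float
TIFF (tifffile).
"""

from __future__ import annotations

import string
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import gemmi
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .falloff import ArrayPopulation, ConditionTable
from .geometry import LatticeModel, PointSet
from .gliding import Track
from .micrograph import Micrograph

__all__ = [
    "write_array_tables",
    "read_array_tables",
    "write_fasta",
    "read_fasta",
    "write_lattice",
    "read_lattice",
    "write_micrograph",
    "read_micrograph",
    "write_tracks",
    "read_tracks",
]

_CHAIN_NAMES = string.ascii_uppercase + string.ascii_lowercase + string.digits


# --- array-length tables ----------------------------------------------------

def write_array_tables(path: str | Path, table: pd.DataFrame) -> None:
    """TSV with columns condition, array_id, n_oads."""
    table[["condition", "array_id", "n_oads"]].to_csv(path, sep="\t", index=False)


def read_array_tables(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"condition": str})
    missing = {"condition", "array_id", "n_oads"} - set(df.columns)
    if missing:
        raise ValueError(f"array table misses columns: {sorted(missing)}")
    return df


def conditions_from_table(
    table: pd.DataFrame, coverages: dict[str, float] | None = None
) -> list[ConditionTable]:
    """Build per-condition observations, preserving first-appearance order."""
    out = []
    for label in dict.fromkeys(table["condition"]):
        lengths = table.loc[table["condition"] == label, "n_oads"].to_numpy()
        cov = coverages.get(label) if coverages else None
        out.append(ConditionTable(label=str(label), lengths=lengths, coverage=cov))
    return out


# --- proteomes --------------------------------------------------------------

def write_fasta(path: str | Path, records: Iterable[SeqRecord]) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def fasta_as_pairs(records: Iterable[SeqRecord]) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in records]


# --- lattices ---------------------------------------------------------------

def write_lattice(path: str | Path, lattice: LatticeModel) -> None:
    """Pseudo-atom model: chain = PF index, residue number = repeat index + 1."""
    st = gemmi.Structure()
    st.name = "lattice"
    model = gemmi.Model("1")
    for pf in lattice.pf_indices():
        chain = gemmi.Chain(_CHAIN_NAMES[pf])
        for rep in lattice.repeat_indices():
            key = (pf, rep)
            if key not in lattice.dimers:
                continue
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(rep + 1, " ")
            for i, xyz in enumerate(lattice.dimers[key].coordinates):
                atom = gemmi.Atom()
                atom.name = "CA"
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*xyz)
                atom.serial = i + 1
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def read_lattice(path: str | Path) -> LatticeModel:
    """Rebuild a LatticeModel; the first dimer read becomes the reference.

    Inter-PF angles are invariant to the reference-dimer choice (relative
    rotations cancel it), so round-tripping preserves every measurement.
    """
    st = gemmi.read_structure(str(path))
    dimers: dict[tuple[int, int], PointSet] = {}
    for chain in st[0]:
        pf = _CHAIN_NAMES.index(chain.name)
        for res in chain:
            rep = res.seqid.num - 1
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
            dimers[(pf, rep)] = PointSet(label=f"pf{pf}_rep{rep}", coordinates=coords)
    if not dimers:
        raise ValueError("no dimers found in structure file")
    reference = dimers[min(dimers)]
    return LatticeModel(dimers=dimers, reference_dimer=reference)


# --- micrographs ------------------------------------------------------------

def write_micrograph(path: str | Path, img: Micrograph) -> None:
    """32-bit float TIFF; the pixel size (Å) is stored in the resolution tag."""
    tifffile.imwrite(
        str(path),
        img.pixels.astype(np.float32),
        description=f"pixel_size_A={img.pixel_size_A}",
    )


def read_micrograph(path: str | Path) -> Micrograph:
    with tifffile.TiffFile(str(path)) as tif:
        pixels = tif.asarray()
        desc = tif.pages[0].description or ""
    pixel_size = 1.0
    for token in desc.split():
        if token.startswith("pixel_size_A="):
            pixel_size = float(token.split("=", 1)[1])
    return Micrograph(pixels=pixels, pixel_size_A=pixel_size)


# --- gliding tracks ---------------------------------------------------------

def write_tracks(path: str | Path, tracks: Sequence[Track]) -> None:
    """TSV with columns track_id, frame, time_s, x_um, y_um."""
    rows = []
    for t in tracks:
        for frame, (time_s, x, y) in enumerate(zip(t.times_s, t.x_um, t.y_um)):
            rows.append(
                {"track_id": t.track_id, "frame": frame, "time_s": time_s,
                 "x_um": x, "y_um": y}
            )
    pd.DataFrame(rows, columns=["track_id", "frame", "time_s", "x_um", "y_um"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_tracks(path: str | Path, frame_rate_hz: float = 13.5) -> list[Track]:
    df = pd.read_csv(path, sep="\t", dtype={"track_id": str})
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=str(tid),
                times_s=grp["time_s"].to_numpy(),
                x_um=grp["x_um"].to_numpy(),
                y_um=grp["y_um"].to_numpy(),
                frame_rate_hz=frame_rate_hz,
            )
        )
    return tracks
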