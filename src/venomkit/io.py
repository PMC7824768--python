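"""File format I/O: FASTA, MGF, minimal mzML, MS1 peak tables, PDB.

Standard formats go through the established parsers (Biopython for FASTA
and PDB, pyteomics for MGF and mzML); this module only adapts them to the
package's in-memory types.
"""

from __future__ import annotations

import warnings

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf
from pyteomics import mzml as _mzml

from .annotate import TranscriptRecord
from .search import Spectrum
from .structure import Residue, StructureModel


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def read_transcripts(path) -> list[TranscriptRecord]:
    records = []
    seen = set()
    for rid, seq in read_fasta(path):
        if rid in seen:
            raise ValueError(f"duplicate transcript id {rid}")
        seen.add(rid)
        records.append(TranscriptRecord(rid, seq))
    return records


def write_fasta(path, records, width: int = 60) -> None:
    seq_records = [SeqRecord(Seq(seq), id=rid, description="")
                   for rid, seq in records]
    with open(path, "w") as fh:
        SeqIO.FastaIO.FastaWriter(fh, wrap=width).write_file(seq_records)


def read_mgf(path) -> list[Spectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params["charge"][0])
            peaks = tuple(zip(entry["m/z array"].tolist(),
                              entry["intensity array"].tolist()))
            spectra.append(Spectrum(
                id=str(params.get("title", f"scan{len(spectra)}")),
                precursor_mz=float(params["pepmass"][0]),
                precursor_charge=charge,
                peaks=peaks))
    return spectra


def write_mgf(path, spectra: list[Spectrum]) -> None:
    entries = []
    for s in spectra:
        entries.append({
            "m/z array": np.array([p[0] for p in s.peaks]),
            "intensity array": np.array([p[1] for p in s.peaks]),
            "params": {"title": s.id, "pepmass": s.precursor_mz,
                       "charge": f"{s.precursor_charge}+"},
        })
    _mgf.write(entries, str(path), file_mode="w")


def read_mzml(path) -> tuple[list[Spectrum], list[tuple]]:
    """Minimal mzML reading: returns (MS2 spectra, MS1 peaks).

    MS1 peaks are flattened (scan index, m/z, intensity) rows; MS2 spectra
    require a selected precursor with a declared charge state.
    """
    ms2 = []
    ms1_rows = []
    with _mzml.MzML(str(path)) as reader:
        for i, entry in enumerate(reader):
            level = entry.get("ms level")
            mzs = entry["m/z array"]
            intens = entry["intensity array"]
            if level == 1:
                for m, it in zip(mzs.tolist(), intens.tolist()):
                    ms1_rows.append((i, m, it))
            elif level == 2:
                try:
                    precursor = entry["precursorList"]["precursor"][0]
                    ion = precursor["selectedIonList"]["selectedIon"][0]
                    pmz = float(ion["selected ion m/z"])
                    charge = int(ion["charge state"])
                except (KeyError, IndexError):
                    warnings.warn(f"MS2 scan {i} lacks precursor info; skipped")
                    continue
                ms2.append(Spectrum(str(entry.get("id", i)), pmz, charge,
                                    tuple(zip(mzs.tolist(), intens.tolist()))))
    return ms2, ms1_rows


def read_ms1_table(path) -> list[tuple]:
    """Tab-separated (scan, mz, intensity) rows, header optional."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            try:
                rows.append((int(fields[0]), float(fields[1]),
                             float(fields[2])))
            except ValueError:
                continue  # header line
    return rows


def write_ms1_table(path, rows) -> None:
    with open(path, "w") as fh:
        fh.write("scan\tmz\tintensity\n")
        for scan, m, it in rows:
            fh.write(f"{scan}\t{m:.6f}\t{it:.4f}\n")


_WANTED_ATOMS = {"N", "CA", "C", "O", "SG", "CB"}


def read_pdb(path, model_index: int = 0) -> StructureModel:
    """Read fixed-column ATOM records into a StructureModel.

    Takes one MODEL of a (possibly multi-model NMR) file, altLoc 'A' or
    blank, author residue numbering preserved.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio = PDBParser(QUIET=True).get_structure("m", str(path))
    models = list(bio)
    model = models[model_index]
    residues = []
    for chain in model:
        for res in chain:
            if res.id[0].strip():
                continue  # HETATM
            name3 = res.get_resname().strip()
            aa = protein_letters_3to1.get(name3.upper(), "X")
            atoms = {}
            for atom in res:
                if atom.get_altloc() not in (" ", "A"):
                    continue
                if atom.get_name() in _WANTED_ATOMS:
                    atoms[atom.get_name()] = np.array(atom.get_coord(),
                                                      dtype=float)
            residues.append(Residue(res.id[1], aa, atoms))
    return StructureModel(tuple(residues))


_AA1TO3 = {v: k for k, v in protein_letters_3to1.items()}


def write_pdb(path, model: StructureModel) -> None:
    """Write a StructureModel as fixed-column ATOM records."""
    order = ["N", "CA", "C", "O", "CB", "SG"]
    with open(path, "w") as fh:
        serial = 1
        for res in model.residues:
            res3 = _AA1TO3.get(res.aa, "UNK")
            for name in order:
                if name not in res.atoms:
                    continue
                x, y, z = res.atoms[name]
                fh.write(
                    f"ATOM  {serial:5d}  {name:<3s}{res3:>4s} A"
                    f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00           {name[0]}\n")
                serial += 1
        fh.write("END\n")
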