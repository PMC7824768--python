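"""End-to-end orchestration: annotate -> digest -> search -> intact -> structure.

A run consumes a validated :class:`RunConfig`, executes each stage whose
inputs are present, and writes a consolidated per-toxin evidence report:
transcript support, bottom-up peptides with coordinates and missed
cleavages, intact-mass match (hypothesis, ppm error, charge states), an
amidation verdict, and structural annotations when coordinates are
supplied.  Amidation counts as confirmed only when the evidence actually
covers the mature C-terminus — an amidated C-terminal proteolytic peptide
or an intact-mass match requiring the amide.

The run directory receives the config serialized verbatim, a log of every
stage's parameters (with a hash of the canonical config, so outputs are
content-addressed), and each stage's tab-separated table.  Reruns with the
same config and seeds are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as vio
from .annotate import (AnnotationError, PrecursorModel, SegmentationConfig,
                       cys_framework, find_orfs, segment_precursor)
from .intact import detect_clusters, intact_table, match_intact
from .masses import Proteoform, monoisotopic_mass
from .search import (FIXED_CAM, PSM, PeptidoformIndex, build_search_db,
                     match_spectrum, target_decoy_fdr)
from .structure import classify_ick, detect_disulfides

logger = logging.getLogger("venomkit")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    transcripts: str | None = None
    msms: dict = field(default_factory=dict)     # enzyme -> MGF path
    ms1: str | None = None
    structure: str | None = None
    out_dir: str = "venomkit_run"
    enzymes: tuple = ("trypsin", "gluc")
    max_missed: int = 4
    prec_tol_ppm: float = 10.0
    frag_tol_da: float = 0.02
    fdr_alpha: float = 0.01
    intact_tol_ppm: float = 5.0
    min_orf_aa: int = 40
    identity_threshold: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.transcripts is None:
            raise ValueError("a transcript FASTA is required")
        for enzyme in self.enzymes:
            if enzyme not in ("trypsin", "gluc"):
                raise ValueError(f"unsupported enzyme {enzyme!r}")
        if not 0 < self.fdr_alpha < 0.5:
            raise ValueError("fdr_alpha must be in (0, 0.5)")
        if self.prec_tol_ppm <= 0 or self.frag_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        for path in [self.transcripts, self.ms1, self.structure,
                     *self.msms.values()]:
            if path is not None and not Path(path).exists():
                raise ValueError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.enzymes, list):
            cfg.enzymes = tuple(cfg.enzymes)
        return cfg

    def canonical(self) -> str:
        data = asdict(self)
        data["enzymes"] = list(self.enzymes)
        return json.dumps(data, sort_keys=True)


def annotate_transcripts(records, min_orf_aa: int,
                         seg_config: SegmentationConfig | None = None
                         ) -> list[tuple[str, PrecursorModel]]:
    """Find ORFs, segment precursors, keep cysteine-containing matures."""
    results = []
    for record in records:
        for orf in find_orfs(record, min_orf_aa):
            try:
                model = segment_precursor(orf, seg_config)
            except AnnotationError as exc:
                logger.debug("%s: %s", record.id, exc)
                continue
            if model.mature_seq.count("C") < 2:
                continue
            results.append((record.id, model))
    return results


def annotation_table(annotated) -> str:
    lines = ["transcript\tsignal\tpropeptide\tmature\ttail\tamidated\t"
             "cys_pattern"]
    for tid, model in annotated:
        fw = cys_framework(model.mature_seq)

        def span(iv):
            return f"{iv.start}-{iv.end}" if iv is not None else "-"

        lines.append("\t".join([
            tid, span(model.signal), span(model.propeptide),
            span(model.mature), span(model.amidation_tail),
            str(model.amidated), fw.pattern or "linear"]))
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory path.

    Raises :class:`PipelineError` naming the failed stage; partial outputs
    written before the failure are preserved in the run directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    canonical = config.canonical()
    config_hash = hashlib.sha256(canonical.encode()).hexdigest()[:16]
    (out / "config.yaml").write_text(
        yaml.safe_dump(json.loads(canonical), sort_keys=True))
    log_lines = [f"config_sha256_16 {config_hash}"]

    def log(stage, **params):
        log_lines.append(
            stage + " " + " ".join(f"{k}={v}" for k, v in sorted(params.items())))

    # --- annotate ---------------------------------------------------------
    try:
        records = vio.read_transcripts(config.transcripts)
        annotated = annotate_transcripts(records, config.min_orf_aa)
        (out / "annotation.tsv").write_text(annotation_table(annotated))
        log("annotate", n_transcripts=len(records),
            n_precursors=len(annotated), min_orf_aa=config.min_orf_aa)
    except Exception as exc:
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineError("annotate", str(exc)) from exc

    precursors = [model for _, model in annotated]
    evidence = {
        tid: {"mature": model.mature_seq, "predicted_amidated": model.amidated,
              "peptides": [], "intact": None, "amidation_confirmed": False,
              "structure": None}
        for tid, model in annotated}

    # --- search -----------------------------------------------------------
    accepted_by_enzyme = {}
    if config.msms:
        try:
            db = build_search_db(precursors)
            acc_to_tid = {}
            for i, (tid, model) in enumerate(annotated):
                acc_to_tid[f"tx{i:04d}|mature"] = (tid, model)
                acc_to_tid[f"tx{i:04d}|propeptide"] = (tid, model)
            for enzyme, mgf_path in config.msms.items():
                spectra = vio.read_mgf(mgf_path)
                index = PeptidoformIndex(db, enzyme, config.max_missed,
                                         fixed=FIXED_CAM)
                psms: list[PSM] = []
                for spectrum in spectra:
                    psms.extend(match_spectrum(
                        spectrum, index, config.prec_tol_ppm,
                        config.frag_tol_da))
                accepted = target_decoy_fdr(psms, config.fdr_alpha)
                accepted_by_enzyme[enzyme] = accepted
                log("search", enzyme=enzyme, n_spectra=len(spectra),
                    n_psms=len(psms), n_accepted=len(accepted),
                    prec_tol_ppm=config.prec_tol_ppm,
                    frag_tol_da=config.frag_tol_da, fdr=config.fdr_alpha)
                lines = ["spectrum\taccession\tpeptide\tfrom\tto\tmissed\t"
                         "mods\tamidated\tscore\tq_value"]
                for psm in accepted:
                    pep = psm.peptidoform.peptide
                    lines.append("\t".join(map(str, [
                        psm.spectrum_id, psm.accession, pep.sequence,
                        pep.start, pep.end, pep.missed_cleavages,
                        psm.peptidoform.mod_label() or "-",
                        psm.peptidoform.c_amidated,
                        f"{psm.score:.3f}", f"{psm.q_value:.4f}"])))
                (out / f"psms_{enzyme}.tsv").write_text(
                    "\n".join(lines) + "\n")
                for psm in accepted:
                    entry = acc_to_tid.get(psm.accession)
                    if entry is None:
                        continue
                    tid, model = entry
                    pep = psm.peptidoform.peptide
                    evidence[tid]["peptides"].append(
                        (enzyme, pep.sequence, pep.start, pep.end,
                         pep.missed_cleavages, psm.peptidoform.c_amidated))
                    if (psm.accession.endswith("|mature")
                            and psm.peptidoform.c_amidated
                            and pep.end == len(model.mature_seq)):
                        evidence[tid]["amidation_confirmed"] = True
        except Exception as exc:
            (out / "run.log").write_text("\n".join(log_lines) + "\n")
            raise PipelineError("search", str(exc)) from exc

    # --- intact -----------------------------------------------------------
    if config.ms1:
        try:
            rows = vio.read_ms1_table(config.ms1)
            peaks = sorted((m, i) for _, m, i in rows)
            clusters = detect_clusters(peaks, min_peaks=3)
            candidates = []
            for tid, model in annotated:
                candidates.append((f"{tid}|mature", model.mature_seq))
                if model.propeptide_seq:
                    candidates.append((f"{tid}|propeptide",
                                       model.propeptide_seq))
            matches = match_intact(clusters, candidates,
                                   tol_ppm=config.intact_tol_ppm)
            (out / "intact.tsv").write_text(intact_table(matches))
            log("intact", n_peaks=len(peaks), n_clusters=len(clusters),
                n_matched=sum(m.matched for m in matches),
                tol_ppm=config.intact_tol_ppm)
            for match in matches:
                if not match.matched or not match.sequence_id.endswith(
                        "|mature"):
                    continue
                tid = match.sequence_id.rsplit("|", 1)[0]
                evidence[tid]["intact"] = (
                    match.n_disulfides, match.c_amidated,
                    round(match.error_ppm, 2), list(match.charge_states))
                if match.c_amidated:
                    evidence[tid]["amidation_confirmed"] = True
        except Exception as exc:
            (out / "run.log").write_text("\n".join(log_lines) + "\n")
            raise PipelineError("intact", str(exc)) from exc

    # --- structure --------------------------------------------------------
    if config.structure:
        try:
            model = vio.read_pdb(config.structure)
            bonds = detect_disulfides(model)
            cys_pos = [r.index for r in model.residues if r.aa == "C"]
            ick = classify_ick(bonds, cys_pos) if bonds else {
                "core": None, "extra_roles": {}}
            summary = {
                "sequence": model.sequence,
                "disulfides": [[b.i, b.j] for b in bonds],
                "ick_core": ([[b.i, b.j] for b in ick["core"]]
                             if ick["core"] else None),
                "extra_roles": {f"{b.i}-{b.j}": role
                                for b, role in ick["extra_roles"].items()},
            }
            (out / "structure.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True) + "\n")
            log("structure", n_disulfides=len(bonds),
                ick=bool(ick["core"]))
            matching = [tid for tid, model_ in annotated
                        if model_.mature_seq == summary["sequence"]]
            for tid in matching:
                evidence[tid]["structure"] = summary
        except Exception as exc:
            (out / "run.log").write_text("\n".join(log_lines) + "\n")
            raise PipelineError("structure", str(exc)) from exc

    # --- consolidated report ---------------------------------------------
    lines = ["transcript\tmature\tn_peptides\tbottom_up\tintact\t"
             "amidation_verdict\tick_core"]
    for tid in sorted(evidence):
        ev = evidence[tid]
        peptides = sorted(set(ev["peptides"]))
        pep_str = ";".join(f"{e}:{s}@{a}-{b}mc{m}{'+NH2' if am else ''}"
                           for e, s, a, b, m, am in peptides) or "-"
        intact = ev["intact"]
        intact_str = (f"{intact[0]}SS{'+NH2' if intact[1] else ''}"
                      f"@{intact[2]}ppm,z={','.join(map(str, intact[3]))}"
                      if intact else "-")
        verdict = ("confirmed" if ev["amidation_confirmed"]
                   else ("predicted" if ev["predicted_amidated"]
                         else "none"))
        ick_str = "-"
        if ev["structure"] and ev["structure"]["ick_core"]:
            ick_str = ";".join(f"{i}-{j}"
                               for i, j in ev["structure"]["ick_core"])
        lines.append("\t".join([tid, ev["mature"], str(len(peptides)),
                                pep_str, intact_str, verdict, ick_str]))
    (out / "report.tsv").write_text("\n".join(lines) + "\n")
    log("report", n_toxins=len(evidence))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
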