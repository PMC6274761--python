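"""Pipeline orchestration: configuration, staged execution and reporting.

Stages run in order sequence-preparation -> coupling analysis -> structure
mapping -> statistics for every configured complex; complexes failing the
family-size gate are reported as excluded (not errors), and a failure in
one complex is recorded and does not stop the others. The report carries a
Table-style per-complex record (coupling counts, interface couplings,
bonded couplings, invisible counts with reasons, distance histogram) plus
run-level totals, and is written atomically as JSON and TSV.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import scoring, stats
from .alignment import PairedAlignment
from .contacts import atomic_contacts
from .interface import assign_interface, load_interface_override
from .plm import fit_mrf
from .scoring import CalibrationCurve, fit_default_calibration
from .secondary import assign_secondary_structure, read_dssp
from .seqprep import (DEFAULT_MIN_LEN, DEFAULT_PFAM_THRESHOLD,
                      build_paired_alignment, pfam_gate, read_msa,
                      sequence_weights)
from .structure import (NumberingMap, classify_visibility,
                        ec_structure_residues, read_structure,
                        residue_min_distance)


@dataclass
class ComplexConfig:
    """Inputs for one complex. Either a ready paired alignment
    (``paired_msa`` + ``boundary``) or two per-protein MSAs with query ids."""

    id: str
    paired_msa: str | None = None
    boundary: int | None = None
    idp_msa: str | None = None
    partner_msa: str | None = None
    query_idp: str | None = None
    query_partner: str | None = None
    structure: str | None = None
    idp_chain: str = "A"
    partner_chains: list[str] = field(default_factory=lambda: ["B"])
    # chain -> (uniprot_start, uniprot_end, resseq_of_start)
    numbering: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    idp_region: tuple[int, int] | None = None  # UniProt coords of analyzed range
    partner_region: tuple[int, int] | None = None
    pfam_count: int | None = None
    dssp_file: str | None = None
    pisa_override: str | None = None


@dataclass
class Thresholds:
    min_len: int = DEFAULT_MIN_LEN
    pfam: int = DEFAULT_PFAM_THRESHOLD
    score_min: float = scoring.SCORE_MIN
    prob_min: float = scoring.PROB_MIN
    n_resamples: int = stats.N_RESAMPLES
    max_fit_iter: int = 500


@dataclass
class RunConfig:
    complexes: list[ComplexConfig] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    out_dir: str = "idpcoev_out"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.complexes]
        if len(set(ids)) != len(ids):
            raise ValueError("complex ids must be unique")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        complexes = [ComplexConfig(**c) for c in raw.pop("complexes", [])]
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        return cls(complexes=complexes, thresholds=thresholds, **raw)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


@dataclass
class AnalysisReport:
    per_complex: dict[str, dict] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    metadata: dict = field(default_factory=dict)
    timestamp: str = ""  # kept separate so reruns are comparable

    def finalize_totals(self) -> None:
        n_ecs = sum(c["n_ecs"] for c in self.per_complex.values())
        n_inv = sum(c["n_invisible"] for c in self.per_complex.values())
        self.totals = {
            "n_ecs_total": n_ecs,
            "n_invisible_total": n_inv,
            "n_visible_total": n_ecs - n_inv,
            "n_bonded_total": sum(c["n_bonded_ecs"]
                                  for c in self.per_complex.values()),
        }

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = dataclasses.asdict(self)
        _atomic_write(out_dir / "report.json",
                      json.dumps(payload, indent=1, default=_json_default))
        lines = ["complex\tif_area\tn_ecs\tn_interface_ecs\tn_bonded_ecs\t"
                 "n_invisible\thist_lt8\thist_8_10\thist_gt10"]
        for cid, c in self.per_complex.items():
            h = c.get("distance_histogram", (0, 0, 0))
            lines.append(f"{cid}\t{c.get('interface_area', 0):.1f}\t{c['n_ecs']}\t"
                         f"{c['n_interface_ecs']}\t{c['n_bonded_ecs']}\t"
                         f"{c['n_invisible']}\t{h[0]}\t{h[1]}\t{h[2]}")
        _atomic_write(out_dir / "report.tsv", "\n".join(lines) + "\n")


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def analyze_complex(cc: ComplexConfig, th: Thresholds, seed: int,
                    calibration: CalibrationCurve) -> dict:
    """Run one complex through coupling analysis, structure mapping and the
    statistical battery; returns the per-complex report record."""
    # --- alignment ---------------------------------------------------------
    if cc.paired_msa:
        aln = PairedAlignment.read(cc.paired_msa, boundary=cc.boundary)
    elif cc.idp_msa and cc.partner_msa:
        aln = build_paired_alignment(read_msa(cc.idp_msa), read_msa(cc.partner_msa),
                                     cc.query_idp, cc.query_partner)
    else:
        raise ValueError(f"{cc.id}: no alignment inputs")
    if aln.weights is None:
        aln.weights = sequence_weights(aln)

    # --- couplings ---------------------------------------------------------
    model = fit_mrf(aln, max_iter=th.max_fit_iter)
    pair_scores = scoring.score_couplings(aln, model, calibration)

    idp_region = partner_region = None
    if cc.idp_region:
        idp_region = _RegionShim(cc.idp_region[0])
    if cc.partner_region:
        partner_region = _RegionShim(cc.partner_region[0])
    ecs = scoring.filter_ecs(pair_scores, aln.boundary, idp_region,
                             partner_region, th.score_min, th.prob_min)

    record: dict = {
        "n_rows": aln.n_rows,
        "effective_n": aln.effective_n,
        "model_converged": model.converged,
        "n_ecs": len(ecs),
        "n_interface_ecs": 0,
        "n_bonded_ecs": 0,
        "n_invisible": 0,
        "invisible_reasons": {},
        "ecs": [dataclasses.asdict(e) for e in ecs],
    }
    if not ecs:
        record["notice"] = "no couplings above thresholds; structural and " \
                           "statistical stages skipped"
        return record
    if not cc.structure:
        record["notice"] = "no structure provided; structural stages skipped"
        return record

    # --- structure mapping -------------------------------------------------
    nmap = NumberingMap.from_offset(cc.numbering) if cc.numbering else None
    s = read_structure(cc.structure, cc.idp_chain, cc.partner_chains, nmap)
    visible_ecs = []
    reasons: dict[str, int] = {}
    for ec in ecs:
        status, reason = classify_visibility(ec, s)
        if status == "visible":
            visible_ecs.append(ec)
        else:
            reasons[reason] = reasons.get(reason, 0) + 1
    record["n_invisible"] = len(ecs) - len(visible_ecs)
    record["invisible_reasons"] = reasons

    iface = (load_interface_override(cc.pisa_override, s) if cc.pisa_override
             else assign_interface(s))
    record["interface_area"] = iface.total_area
    record["bonds_per_1000A2"] = iface.bonds_per_1000A2
    cmap = atomic_contacts(s) if not s.is_nmr else None
    record["is_nmr"] = s.is_nmr
    ss = read_dssp(cc.dssp_file, s) if cc.dssp_file else assign_secondary_structure(s)

    bonded_pairs = {(i, j) for i, j, _ in iface.hbonds}
    bonded_pairs |= {(i, j) for i, j, _ in iface.salt_bridges}
    bonded_idp = {i for i, _ in bonded_pairs}

    ec_pairs = []
    ec_distances = []
    n_if = 0
    n_bonded = 0
    for ec in visible_ecs:
        pair = ec_structure_residues(ec, s)
        if pair is None:
            continue
        ri, rj = pair
        ec_pairs.append(pair)
        ec_distances.append(residue_min_distance(s, ri, rj))
        if ri in iface.idp_if_residues:
            n_if += 1
        if ri in bonded_idp:
            n_bonded += 1
    record["n_interface_ecs"] = n_if
    record["n_bonded_ecs"] = n_bonded
    record["ec_distances"] = ec_distances
    record["distance_histogram"] = stats.distance_histogram(ec_distances)

    # --- statistics --------------------------------------------------------
    if ec_pairs and iface.idp_if_residues and iface.partner_if_residues:
        samples = stats.random_pair_null(s, iface, ec_pairs,
                                         n_resamples=th.n_resamples, seed=seed)
        record["distance_null"] = {
            k: v for k, v in stats.compare_ec_distances(ec_distances, samples).items()
            if k != "p_values"
        }
        record["null_summary_sd"] = stats.null_summary_variation(samples)

    # raw residue multisets for the run-level composition analysis
    # (identical partner chains are merged by residue number already)
    ec_idp_res = {ri for ri, _ in ec_pairs}
    record["composition_sets"] = {
        "idp_interface": [s.residues[r].aa for r in iface.idp_if_residues],
        "partner_interface": [s.residues[r].aa for r in iface.partner_if_residues],
        "idp_ec_residues": [s.residues[r].aa for r in sorted(ec_idp_res)],
        "partner_ec_residues": [s.residues[r].aa
                                for r in sorted({rj for _, rj in ec_pairs})],
        "idp_analyzed_range": [s.residues[r].aa
                               for r in s.chain_residue_indices(s.idp_chain)],
    }
    other_idp = [r for r in s.chain_residue_indices(s.idp_chain)
                 if r not in ec_idp_res and s.atom_indices(r)]
    record["ss_preference_idp"] = stats.ss_preference(ss, sorted(ec_idp_res),
                                                      other_idp)
    if cmap is not None:
        record["ec_contact_counts"] = [
            cmap.entries.get((s.residues[ri].resseq, s.residues[rj].resseq), 0)
            for ri, rj in ec_pairs
        ]
    return record


def _run_level_composition(report: "AnalysisReport") -> None:
    """Pool the per-complex residue multisets into the standard composition
    categories (IDP side): analyzed ranges, all interfaces, interfaces of
    EC-bearing vs EC-free complexes, and EC residues."""
    cats = {c: [] for c in stats.CATEGORIES}
    for rec in report.per_complex.values():
        sets = rec.get("composition_sets")
        if not sets:
            continue
        cats["analyzed_range"] += sets["idp_analyzed_range"]
        cats["all_IF"] += sets["idp_interface"]
        if rec["n_ecs"] > 0:
            cats["EC_IF"] += sets["idp_interface"]
            cats["EC_residues"] += sets["idp_ec_residues"]
        else:
            cats["noEC_IF"] += sets["idp_interface"]
    if any(cats.values()):
        result = stats.composition_analysis(cats)
        report.metadata["idp_composition"] = {
            "fractions": {c: result["table"][c].dropna().to_dict()
                          for c in result["table"].columns},
            "p_values": {f"{a}_vs_{b}_{g}": p
                         for (a, b, g), p in result["p_values"].items()},
        }


class _RegionShim:
    """Minimal column->UniProt offset mapping for filter_ecs."""

    def __init__(self, uniprot_start: int):
        self.start = uniprot_start

    def to_uniprot(self, column: int) -> int:
        return self.start + column - 1


def run_pipeline(config: RunConfig,
                 calibration: CalibrationCurve | None = None) -> AnalysisReport:
    """Run every configured complex through the full pipeline.

    Complexes below the family-size threshold are reported under
    ``excluded``; other per-complex failures land under ``errors`` and do
    not abort the run. Deterministic for a fixed config and seed.
    """
    report = AnalysisReport(seed=config.seed, metadata=dict(config.metadata))
    report.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    if calibration is None:
        calibration = fit_default_calibration(seed=config.seed)
    for cc in config.complexes:
        if cc.pfam_count is not None and not pfam_gate(cc.pfam_count,
                                                       config.thresholds.pfam):
            report.excluded[cc.id] = (
                f"excluded (<{config.thresholds.pfam} family sequences: "
                f"{cc.pfam_count})")
            continue
        try:
            report.per_complex[cc.id] = analyze_complex(
                cc, config.thresholds, config.seed, calibration)
        except Exception as exc:  # keep going; record the failure
            report.errors[cc.id] = f"{type(exc).__name__}: {exc}"
    _run_level_composition(report)
    report.finalize_totals()
    report.write(config.out_dir)
    return report
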