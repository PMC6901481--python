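"""End-to-end orchestration: simulate inputs, run differential proteomics
and phosphoproteomics, network proximity, metabolomics and the functional
assay statistics, and record everything in a run manifest.

Stages run in a fixed order and each stage's outputs are written before the
next begins, so a later failure preserves earlier results. The manifest
echoes the configuration, the seed, per-stage status and a SHA-256 digest
of every written file; reruns with the same seed reproduce the digests.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assays, diffexpr, metabnet, omics_io, proximity, synthio
from .interactome import build_interactome
from .omics_io import read_edge_list, read_gmt, read_intensity_tsv, \
    read_sample_sheet
from .proximity import NodeSet, ProximityAnalysis, overlap_fisher
from .synthio import SimConfig, stage_rng

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de_proteome", "de_phospho", "proximity",
          "metabolomics", "assays")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthio": {},                 # overrides for SimConfig fields
    "de": {"alpha": 0.05, "rule": "raw_p", "k": 10,
           "localization_threshold": 0.5},
    "proximity": {"n_perm": 2000, "min_bin_size": None, "mito_pass": True,
                  "mito_fraction": 0.5},
    "metabolomics": {"enabled": True, "alpha": 0.05, "max_hops": 2},
    "assays": {"enabled": True, "n_boot": 10000},
}


def default_config(seed: int = 0, **synthio_overrides) -> dict:
    cfg = _deep_merge(DEFAULT_CONFIG, {})
    cfg["seed"] = seed
    cfg["synthio"].update(synthio_overrides)
    return cfg


def _deep_merge(base: Mapping, override: Mapping) -> dict:
    out = {}
    for key, val in base.items():
        out[key] = dict(val) if isinstance(val, Mapping) else val
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key].update(val)
        else:
            out[key] = val
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    return _deep_merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class RunManifest:
    """Config echo, per-stage status and digests for every written file."""

    def __init__(self, config: dict, out_dir: Path):
        self.config = config
        self.out_dir = Path(out_dir)
        self.stages: dict[str, dict] = {
            s: {"status": "pending", "outputs": {}} for s in STAGES}

    def record(self, stage: str, status: str,
               outputs: list[Path] | None = None,
               error: str | None = None) -> None:
        entry = self.stages[stage]
        entry["status"] = status
        if error:
            entry["error"] = error
        for path in outputs or []:
            rel = str(Path(path).relative_to(self.out_dir))
            if rel in entry["outputs"]:
                raise RuntimeError(f"{rel} written twice by stage {stage}")
            entry["outputs"][rel] = _sha256(Path(path))

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.config["seed"],
            "package_version": __version__,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                         "python": sys.version.split()[0]},
            "stages": self.stages,
        }

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        omics_io.write_json(self.to_dict(), path)
        return path

    def verify_digests(self) -> bool:
        for entry in self.stages.values():
            for rel, digest in entry["outputs"].items():
                if _sha256(self.out_dir / rel) != digest:
                    return False
        return True


# --------------------------------------------------------------------------
# stage implementations

def simulate_inputs(config: dict, out_dir: Path) -> list[Path]:
    """Generate and write every synthetic input file for one run.

    The truly differential proteome features and phosphopeptide parents are
    planted as a network-proximal node-set pair so the downstream proximity
    stage sees the structure the analysis is meant to detect.
    """
    out = Path(out_dir) / "sim"
    out.mkdir(parents=True, exist_ok=True)
    scfg = SimConfig(seed=config["seed"], **config.get("synthio", {}))
    written: list[Path] = []

    net = synthio.generate_interactome(scfg)
    omics_io.write_edge_list(net.export_edges(), out / "interactome.tsv")
    written.append(out / "interactome.tsv")

    n_de_prot = max(1, int(round(scfg.frac_de * scfg.n_features)))
    n_de_phos = max(1, int(round(scfg.frac_de * scfg.n_phospho)))
    pair_rng = stage_rng(scfg.seed, "planted_pair")
    set_a, set_b = synthio.generate_node_set_pair(
        net, n_de_prot, n_de_phos, mode="proximal", rng=pair_rng)

    # proteome features are interactome proteins; planted DE = set A
    feat_rng = stage_rng(scfg.seed, "proteome_features")
    nodes = np.array(net.sorted_nodes(), dtype=object)
    non_a = np.array(sorted(set(nodes) - set_a.members), dtype=object)
    n_other = scfg.n_features - n_de_prot
    if n_other > len(non_a):
        raise synthio.SynthIOError(
            "n_features exceeds interactome size; increase n_nodes")
    others = non_a[feat_rng.choice(len(non_a), size=n_other, replace=False)]
    feature_ids = sorted(set_a.members | set(others))
    prot = synthio.generate_intensity_matrix(
        scfg, feature_ids=feature_ids, de_features=sorted(set_a.members))
    omics_io.write_intensity_tsv(prot.matrix, out / "proteome.tsv")
    omics_io.write_sample_sheet(prot.groups, out / "proteome_samples.tsv")
    omics_io.write_results_tsv(prot.truth, out / "proteome_truth.tsv")
    written += [out / "proteome.tsv", out / "proteome_samples.tsv",
                out / "proteome_truth.tsv"]

    # phosphopeptides map many-to-one onto parent proteins; the first |B|
    # peptides carry the planted phospho-DE parents
    parent_pool = sorted(set_b.members) + list(
        nodes[stage_rng(scfg.seed, "phospho_parents").choice(
            len(nodes), size=max(1, scfg.n_nodes // 4), replace=False)])
    sites, phos = synthio.generate_phospho_sites(
        scfg, parent_proteins=parent_pool,
        de_peptides=[f"pp{i + 1:05d}" for i in range(n_de_phos)])
    omics_io.write_results_tsv(sites, out / "phospho_sites.tsv")
    omics_io.write_intensity_tsv(phos.matrix, out / "phospho.tsv")
    omics_io.write_sample_sheet(phos.groups, out / "phospho_samples.tsv")
    omics_io.write_results_tsv(phos.truth, out / "phospho_truth.tsv")
    written += [out / "phospho_sites.tsv", out / "phospho.tsv",
                out / "phospho_samples.tsv", out / "phospho_truth.tsv"]

    # mitochondrial annotation: about half of each planted set plus randoms
    mito_rng = stage_rng(scfg.seed, "mito")
    frac = config["proximity"].get("mito_fraction", 0.5)
    mito: set[str] = set()
    for s in (sorted(set_a.members), sorted(set_b.members)):
        n_pick = max(2, int(round(frac * len(s))))
        mito |= set(np.array(s, dtype=object)[
            mito_rng.choice(len(s), size=min(n_pick, len(s)), replace=False)])
    extra = mito_rng.choice(len(nodes), size=scfg.n_nodes // 10, replace=False)
    mito |= set(nodes[extra])
    pd.DataFrame({"protein_id": sorted(mito)}).to_csv(
        out / "mito_proteins.tsv", sep="\t", index=False, lineterminator="\n")
    written.append(out / "mito_proteins.tsv")

    metab, gmt = synthio.generate_metabolome(scfg)
    omics_io.write_intensity_tsv(metab.matrix, out / "metabolome.tsv")
    omics_io.write_sample_sheet(metab.groups, out / "metabolome_samples.tsv")
    omics_io.write_results_tsv(metab.truth, out / "metabolome_truth.tsv")
    omics_io.write_gmt(gmt, out / "pathways.gmt")
    written += [out / "metabolome.tsv", out / "metabolome_samples.tsv",
                out / "metabolome_truth.tsv", out / "pathways.gmt"]

    # reaction network enzymes: planted DE proteins over-represented so the
    # dysregulated mapping has something to find
    enz_rng = stage_rng(scfg.seed, "enzymes")
    n_from_a = min(len(set_a.members), scfg.n_enzymes // 3)
    enz = set(np.array(sorted(set_a.members), dtype=object)[
        enz_rng.choice(len(set_a.members), size=n_from_a, replace=False)])
    pool = np.array(sorted(set(nodes) - enz), dtype=object)
    enz |= set(pool[enz_rng.choice(len(pool), size=scfg.n_enzymes - len(enz),
                                   replace=False)])
    metabolite_ids = [f for f in metab.matrix.feature_ids
                      if not f.startswith("UNK")]
    reactions = synthio.generate_reaction_network(
        scfg, sorted(enz), metabolite_ids)
    omics_io.write_results_tsv(reactions, out / "reactions.tsv")
    written.append(out / "reactions.tsv")

    tables = synthio.generate_dose_response(scfg)
    for measure, table in tables.items():
        omics_io.write_results_tsv(table, out / f"dose_response_{measure}.tsv")
        written.append(out / f"dose_response_{measure}.tsv")
    return written


def _run_de(matrix_path: Path, samples_path: Path, de_cfg: dict,
            out_path: Path) -> tuple[diffexpr.DEcounts, pd.DataFrame]:
    groups = read_sample_sheet(samples_path)
    m = read_intensity_tsv(matrix_path, groups)
    counts, results = diffexpr.run_de_pipeline(
        m, k=de_cfg["k"], alpha=de_cfg["alpha"], rule=de_cfg["rule"])
    omics_io.write_results_tsv(results, out_path)
    return counts, results


def run_de_proteome(config: dict, out_dir: Path) -> list[Path]:
    out = Path(out_dir)
    counts, _ = _run_de(out / "sim" / "proteome.tsv",
                        out / "sim" / "proteome_samples.tsv",
                        config["de"], out / "de" / "proteome_de.tsv")
    logger.info("proteome: %d significant (%d up, %d down)",
                counts.n_sig, counts.n_up, counts.n_down)
    return [out / "de" / "proteome_de.tsv"]


def run_de_phospho(config: dict, out_dir: Path) -> list[Path]:
    out = Path(out_dir)
    de_cfg = config["de"]
    sites = pd.read_csv(out / "sim" / "phospho_sites.tsv", sep="\t")
    retained = diffexpr.filter_localized(
        sites, threshold=de_cfg["localization_threshold"])
    tally = diffexpr.tally_residues(retained)
    omics_io.write_results_tsv(tally, out / "de" / "residue_tally.tsv")
    groups = read_sample_sheet(out / "sim" / "phospho_samples.tsv")
    m = read_intensity_tsv(out / "sim" / "phospho.tsv", groups)
    retained_ids = set(retained["peptide_id"])
    keep = [f for f in m.feature_ids if f in retained_ids]
    m = m.copy_with(m.values.loc[keep])
    counts, results = diffexpr.run_de_pipeline(
        m, k=de_cfg["k"], alpha=de_cfg["alpha"], rule=de_cfg["rule"])
    results = results.merge(
        retained[["peptide_id", "protein_id", "residue"]]
        if "protein_id" in retained.columns else retained[["peptide_id",
                                                           "residue"]],
        left_on="feature_id", right_on="peptide_id", how="left")
    omics_io.write_results_tsv(results.drop(columns=["peptide_id"]),
                               out / "de" / "phospho_de.tsv")
    logger.info("phospho: %d retained sites, %d significant peptides",
                len(retained), counts.n_sig)
    return [out / "de" / "residue_tally.tsv", out / "de" / "phospho_de.tsv"]


def _de_protein_sets(out_dir: Path) -> tuple[NodeSet, NodeSet]:
    out = Path(out_dir)
    prot = pd.read_csv(out / "de" / "proteome_de.tsv", sep="\t")
    phos = pd.read_csv(out / "de" / "phospho_de.tsv", sep="\t")
    de_prot = prot.loc[prot["direction"] != "ns", "feature_id"]
    if "protein_id" in phos.columns:
        de_phos = phos.loc[phos["direction"] != "ns", "protein_id"].dropna()
    else:
        de_phos = phos.loc[phos["direction"] != "ns", "feature_id"]
    return (NodeSet("de_proteins", de_prot),
            NodeSet("de_phospho_proteins", de_phos))


def run_proximity_stage(config: dict, out_dir: Path) -> list[Path]:
    out = Path(out_dir)
    pcfg = config["proximity"]
    records = read_edge_list(out / "sim" / "interactome.tsv")
    net = build_interactome(records)
    set_a, set_b = _de_protein_sets(out)
    analysis = ProximityAnalysis(net, use_lcc=True,
                                 min_bin_size=pcfg["min_bin_size"])
    written = []
    result = analysis.permutation_test(set_a, set_b, n_perm=pcfg["n_perm"],
                                       seed=config["seed"])
    omics_io.write_json(result.to_dict(), out / "proximity" / "full.json")
    written.append(out / "proximity" / "full.json")
    k, p_fisher = overlap_fisher(set_a, set_b, analysis.net.nodes)
    omics_io.write_json({"overlap": k, "p": p_fisher,
                         "n_a": len(set_a), "n_b": len(set_b),
                         "universe": analysis.net.n_nodes},
                        out / "proximity" / "overlap_fisher.json")
    written.append(out / "proximity" / "overlap_fisher.json")
    if pcfg.get("mito_pass", True):
        mito = set(pd.read_csv(out / "sim" / "mito_proteins.tsv",
                               sep="\t")["protein_id"])
        mito_a = NodeSet("mito_de_proteins", set_a.members & mito)
        mito_b = NodeSet("mito_de_phospho", set_b.members & mito)
        if mito_a.members and mito_b.members:
            mres = analysis.permutation_test(
                mito_a, mito_b, n_perm=pcfg["n_perm"],
                seed=config["seed"] + 1)
            omics_io.write_json(mres.to_dict(),
                                out / "proximity" / "mito.json")
            written.append(out / "proximity" / "mito.json")
        else:
            logger.warning("mitochondrial pass skipped: empty mapped set")
    return written


def run_metabolomics_stage(config: dict, out_dir: Path) -> list[Path]:
    out = Path(out_dir)
    mcfg = config["metabolomics"]
    groups = read_sample_sheet(out / "sim" / "metabolome_samples.tsv")
    m = read_intensity_tsv(out / "sim" / "metabolome.tsv", groups)
    diff = metabnet.metabolite_diff(m, alpha=mcfg["alpha"])
    omics_io.write_results_tsv(diff, out / "metab" / "metabolite_de.tsv")
    gmt = read_gmt(out / "sim" / "pathways.gmt")
    enrich = metabnet.pathway_enrichment(diff, gmt,
                                         alpha_member=mcfg["alpha"])
    omics_io.write_results_tsv(enrich, out / "metab" / "enrichment.tsv")
    reactions = pd.read_csv(out / "sim" / "reactions.tsv", sep="\t")
    net = metabnet.build_met_enz_network(reactions)
    prot = pd.read_csv(out / "de" / "proteome_de.tsv", sep="\t")
    sig_enz = NodeSet("sig_enzymes",
                      prot.loc[prot["direction"] != "ns", "feature_id"])
    sig_met = NodeSet("sig_metabolites",
                      diff.loc[diff["direction"] != "ns", "feature_id"])
    _, components = metabnet.map_dysregulated(net, sig_enz, sig_met,
                                              max_hops=mcfg["max_hops"])
    omics_io.write_results_tsv(components,
                               out / "metab" / "dysregulated_components.tsv")
    return [out / "metab" / "metabolite_de.tsv",
            out / "metab" / "enrichment.tsv",
            out / "metab" / "dysregulated_components.tsv"]


def run_assays_stage(config: dict, out_dir: Path) -> list[Path]:
    out = Path(out_dir)
    acfg = config["assays"]
    ocr = pd.read_csv(out / "sim" / "dose_response_OCR.tsv", sep="\t")
    curves = assays.curves_from_table(ocr)
    case = [c for c in curves if c.group == "case"]
    ctrl = [c for c in curves if c.group == "control"]
    basal_case = [c.responses[0] for c in case]
    basal_ctrl = [c.responses[0] for c in ctrl]
    w, p_wilcoxon = assays.wilcoxon_exact(basal_case, basal_ctrl)
    results = {"basal_ocr": {
        "case_mean": float(np.mean(basal_case)),
        "control_mean": float(np.mean(basal_ctrl)),
        "n_case": len(case), "n_control": len(ctrl),
        "rank_sum": w, "p": p_wilcoxon}}
    for measure in ("OCR", "ECAR"):
        table = pd.read_csv(out / f"sim/dose_response_{measure}.tsv",
                            sep="\t")
        cs = assays.curves_from_table(table)
        boot = assays.bootstrap_auc_compare(
            [c for c in cs if c.group == "case"],
            [c for c in cs if c.group == "control"],
            n_boot=acfg["n_boot"], seed=config["seed"])
        results[f"auc_{measure.lower()}"] = {
            "delta_auc": boot.delta_auc, "p": boot.p,
            "n_boot": boot.n_boot}
    omics_io.write_json(results, out / "assays" / "assays.json")
    return [out / "assays" / "assays.json"]


# --------------------------------------------------------------------------

_STAGE_FUNCS = {
    "simulate": simulate_inputs,
    "de_proteome": run_de_proteome,
    "de_phospho": run_de_phospho,
    "proximity": run_proximity_stage,
    "metabolomics": run_metabolomics_stage,
    "assays": run_assays_stage,
}


def run_full(config, out_dir) -> RunManifest:
    """Run every stage in order, recording outputs and failures in the
    manifest; a disabled stage is marked skipped."""
    config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config, out_dir)
    for stage in STAGES:
        enabled = True
        if stage in ("metabolomics", "assays"):
            enabled = config[stage].get("enabled", True)
        if not enabled:
            manifest.record(stage, "skipped")
            logger.info("stage %s skipped", stage)
            continue
        try:
            outputs = _STAGE_FUNCS[stage](config, out_dir)
        except Exception as exc:
            manifest.record(stage, "error", error=f"{type(exc).__name__}: {exc}")
            manifest.write()
            raise
        manifest.record(stage, "ok", outputs=outputs)
        logger.info("stage %s ok (%d output file(s))", stage, len(outputs))
    manifest.write()
    return manifest
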