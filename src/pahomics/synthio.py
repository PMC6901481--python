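"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator derives its own random substream from the single root seed
plus a stage-name hash, so adding one stage never perturbs another stage's
draws and identical configurations reproduce byte-identical outputs.

The defaults emulate the study conditions: a ~2,556-protein label-free
matrix for 4 case vs 5 control samples with intensity-dependent (MNAR)
missingness, ~3,609 phosphopeptides with S/T/Y localization probabilities,
a scale-free (preferential-attachment) interactome at desk scale, plasma
metabolite profiles for 30 vs 12 subjects, and glucose dose-response
OCR/ECAR curves for 10 vs 9 cell lines.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .interactome import Interactome
from .omics_io import GeneSetCollection, IntensityMatrix
from .proximity import NodeSet


class SynthIOError(ValueError):
    pass


#: Observed S/T/Y proportions among localized phosphosites in the study.
DEFAULT_RESIDUE_PROPS = (0.843, 0.147, 0.010)

#: Glucose doses (mM) of the dose-response assay.
DEFAULT_DOSES = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)

DEFAULT_EVIDENCE_PROBS = {
    "LIT": 0.40, "APMS": 0.25, "Y2H": 0.15, "KS": 0.08, "SIG": 0.07,
    "3D": 0.05,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-scale simulation settings; one root seed drives everything."""

    seed: int = 0
    # proteome / phosphoproteome
    n_features: int = 2556
    n_samples_per_group: tuple[int, int] = (4, 5)   # (case, control)
    frac_de: float = 170 / 2556
    effect_log2fc: float = 1.0
    noise_sd: float = 0.25         # log2-scale multiplicative noise (~19% CV)
    additive_sd: float = 2.0 ** 14  # raw-scale background noise
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    mnar_steepness: float = 1.0
    mnar_midpoint: float = 16.0    # log2 intensity of 50% dropout
    mcar_rate: float = 0.02
    n_phospho: int = 3609
    residue_props: tuple[float, float, float] = DEFAULT_RESIDUE_PROPS
    # interactome
    n_nodes: int = 3000
    edges_per_node: int = 3
    # metabolomics
    n_metabolites: int = 600
    frac_unnamed: float = 0.19
    metab_samples_per_group: tuple[int, int] = (30, 12)
    metab_frac_de: float = 0.2
    metab_effect_log2fc: float = 1.0
    metab_noise_sd: float = 0.8
    pathway_count: int = 25
    pathway_size_range: tuple[int, int] = (8, 40)
    n_enriched_pathways: int = 5
    enriched_member_frac: float = 0.6
    # reactions
    n_reactions: int = 200
    n_enzymes: int = 150
    # dose-response assay
    doses: tuple[float, ...] = DEFAULT_DOSES
    assay_subjects_per_group: tuple[int, int] = (10, 9)  # (case, control)
    ocr_control_mean: float = 72.0
    ocr_case_shift: float = -28.0
    ecar_control_mean: float = 30.0
    ecar_case_shift: float = 10.0
    assay_subject_sd: float = 10.0
    assay_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in ("n_features", "n_phospho", "n_nodes", "edges_per_node",
                     "n_metabolites", "pathway_count", "n_reactions",
                     "n_enzymes"):
            if getattr(self, name) < 1:
                raise SynthIOError(f"{name} must be positive")
        for pair in ("n_samples_per_group", "metab_samples_per_group",
                     "assay_subjects_per_group"):
            a, b = getattr(self, pair)
            if a < 1 or b < 1:
                raise SynthIOError(f"{pair} entries must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise SynthIOError("frac_de must lie in [0, 1]")
        if self.effect_log2fc < 0 or self.noise_sd < 0:
            raise SynthIOError("effect and noise must be non-negative")
        if abs(sum(self.residue_props) - 1.0) > 1e-9:
            raise SynthIOError("residue proportions must sum to 1")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for one generator stage."""
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.default_rng([int(seed), h])


def _sample_ids(n_case: int, n_control: int) -> tuple[list[str], dict[str, str]]:
    case = [f"PAH_{i + 1}" for i in range(n_case)]
    ctrl = [f"CTRL_{i + 1}" for i in range(n_control)]
    groups = {**{s: "case" for s in case}, **{s: "control" for s in ctrl}}
    return case + ctrl, groups


@dataclass
class SimulatedIntensities:
    """A masked intensity matrix plus its complete version and DE truth."""

    matrix: IntensityMatrix
    complete: pd.DataFrame          # raw scale, no missingness
    truth: pd.DataFrame             # feature_id, true_log2fc, is_de
    groups: dict[str, str] = field(default_factory=dict)


def _simulate_lognormal(cfg: SimConfig, rng: np.random.Generator,
                        feature_ids: Sequence[str],
                        n_case: int, n_control: int, frac_de: float,
                        effect: float, noise_sd: float,
                        de_features: Iterable[str] | None,
                        apply_mnar: bool) -> SimulatedIntensities:
    n = len(feature_ids)
    samples, groups = _sample_ids(n_case, n_control)
    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=n)
    if de_features is not None:
        de_features = [str(f) for f in de_features]
        unknown = set(de_features) - set(feature_ids)
        if unknown:
            raise SynthIOError(f"de_features not simulated: {sorted(unknown)[:3]}")
        is_de = np.isin(np.asarray(feature_ids, dtype=object),
                        np.asarray(de_features, dtype=object))
    else:
        n_de = int(round(frac_de * n))
        if frac_de > 0 and n_de < 1:
            raise SynthIOError("frac_de * n_features must be >= 1 when DE "
                               "is requested")
        is_de = np.zeros(n, dtype=bool)
        is_de[rng.choice(n, size=n_de, replace=False)] = True
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    true_fc = np.where(is_de, sign * effect, 0.0)
    latent = base[:, None] + rng.normal(0.0, noise_sd, size=(n, len(samples)))
    case_cols = np.array([groups[s] == "case" for s in samples])
    latent[:, case_cols] += true_fc[:, None]
    raw = np.exp2(latent)
    if cfg.additive_sd > 0:
        raw = np.maximum(raw + rng.normal(0.0, cfg.additive_sd, raw.shape), 0.0)
    complete = pd.DataFrame(raw, index=list(feature_ids), columns=samples)
    values = complete.copy()
    if apply_mnar:
        if np.isneginf(cfg.mnar_midpoint):
            p_mnar = np.zeros_like(latent)
        else:
            p_mnar = expit(-cfg.mnar_steepness * (latent - cfg.mnar_midpoint))
        p_miss = p_mnar + (1.0 - p_mnar) * cfg.mcar_rate
        miss = rng.random(latent.shape) < p_miss
        # keep the invariant of >=1 observation per feature: unmask the
        # highest-latent cell of any fully masked row
        all_missing = miss.all(axis=1)
        if all_missing.any():
            best = latent.argmax(axis=1)
            miss[all_missing, best[all_missing]] = False
        values = values.mask(pd.DataFrame(miss, index=values.index,
                                          columns=values.columns))
    matrix = IntensityMatrix(values=values, groups=groups, transformed=False)
    truth = pd.DataFrame({"feature_id": list(feature_ids),
                          "true_log2fc": true_fc, "is_de": is_de})
    return SimulatedIntensities(matrix=matrix, complete=complete, truth=truth,
                                groups=groups)


def generate_intensity_matrix(cfg: SimConfig, *,
                              feature_ids: Sequence[str] | None = None,
                              de_features: Iterable[str] | None = None,
                              stage: str = "proteome") -> SimulatedIntensities:
    """Log-normal LFQ-like matrix with DE structure and MNAR missingness."""
    rng = stage_rng(cfg.seed, stage)
    if feature_ids is None:
        feature_ids = [f"P{i + 1:05d}" for i in range(cfg.n_features)]
    n_case, n_control = cfg.n_samples_per_group
    return _simulate_lognormal(cfg, rng, feature_ids, n_case, n_control,
                               cfg.frac_de, cfg.effect_log2fc, cfg.noise_sd,
                               de_features, apply_mnar=True)


def generate_phospho_sites(cfg: SimConfig, *,
                           parent_proteins: Sequence[str] | None = None,
                           de_peptides: Iterable[str] | None = None,
                           stage: str = "phospho"
                           ) -> tuple[pd.DataFrame, SimulatedIntensities]:
    """Phosphosite table (residue, localization probability) plus peptide
    intensity matrix.

    Residues are drawn from ``cfg.residue_props`` (S, T, Y); localization
    probabilities come from a mixture with mass on both sides of 0.5 so the
    >50% filter has work to do. Parent proteins, when given, are assigned
    cyclically so every listed protein carries at least one peptide.
    """
    props = np.asarray(cfg.residue_props, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise SynthIOError("residue proportions must sum to 1")
    rng = stage_rng(cfg.seed, stage + "_sites")
    n = cfg.n_phospho
    peptide_ids = [f"pp{i + 1:05d}" for i in range(n)]
    residues = np.array(["S", "T", "Y"], dtype=object)[
        rng.choice(3, size=n, p=props)]
    confident = rng.random(n) < 0.85
    probs = np.where(confident, rng.beta(8.0, 1.0, size=n),
                     rng.beta(1.5, 1.5, size=n))
    n_sites = rng.integers(1, 4, size=n)
    sites = pd.DataFrame({
        "peptide_id": peptide_ids,
        "residue": residues,
        "localization_prob": probs,
        "n_sites_on_peptide": n_sites,
    })
    if parent_proteins is not None:
        parents = [parent_proteins[i % len(parent_proteins)] for i in range(n)]
        sites["protein_id"] = parents
    mrng = stage_rng(cfg.seed, stage + "_matrix")
    n_case, n_control = cfg.n_samples_per_group
    sim = _simulate_lognormal(cfg, mrng, peptide_ids, n_case, n_control,
                              cfg.frac_de, cfg.effect_log2fc, cfg.noise_sd,
                              de_peptides, apply_mnar=True)
    return sites, sim


def generate_interactome(cfg: SimConfig, stage: str = "interactome"
                         ) -> Interactome:
    """Preferential-attachment (scale-free) PPI graph with evidence codes."""
    if cfg.n_nodes < 10:
        raise SynthIOError("need at least 10 nodes")
    rng = stage_rng(cfg.seed, stage)
    g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.edges_per_node,
                                 seed=int(rng.integers(2 ** 31)))
    mapping = {i: f"G{i + 1:05d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    codes = sorted(DEFAULT_EVIDENCE_PROBS)
    probs = np.array([DEFAULT_EVIDENCE_PROBS[c] for c in codes])
    probs = probs / probs.sum()
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    assigned = rng.choice(len(codes), size=len(edges), p=probs)
    out = nx.Graph()
    for (u, v), ci in zip(edges, assigned):
        out.add_edge(u, v, evidence=frozenset({codes[ci]}))
    return Interactome(out)


def generate_node_set_pair(net: Interactome, size_a: int, size_b: int,
                           mode: str, rng: np.random.Generator,
                           radius: int = 1) -> tuple[NodeSet, NodeSet]:
    """Positive/negative control node-set pairs for the proximity test.

    ``proximal`` draws both sets (disjointly) from a breadth-first ball
    around a random anchor; the radius grows automatically until some ball
    can hold both sets. ``random`` samples the pair uniformly.
    """
    order = net.sorted_nodes()
    need = size_a + size_b
    if need > net.n_nodes:
        raise SynthIOError("sets larger than the graph")
    if mode == "random":
        pool = np.array(order, dtype=object)
        picked = rng.choice(len(pool), size=need, replace=False)
        chosen = pool[picked]
    elif mode == "proximal":
        g = net.graph
        while True:
            balls = {n: nx.single_source_shortest_path_length(g, n,
                                                              cutoff=radius)
                     for n in order}
            candidates = [n for n in order if len(balls[n]) >= need]
            if candidates:
                break
            radius += 1
        anchor = candidates[int(rng.integers(len(candidates)))]
        ball = np.array(sorted(balls[anchor]), dtype=object)
        picked = rng.choice(len(ball), size=need, replace=False)
        chosen = ball[picked]
    else:
        raise SynthIOError(f"unknown mode {mode!r}")
    return (NodeSet("A", chosen[:size_a]), NodeSet("B", chosen[size_a:]))


def generate_metabolome(cfg: SimConfig, stage: str = "metabolome"
                        ) -> tuple[SimulatedIntensities, GeneSetCollection]:
    """Metabolite abundance matrix, DE truth and a pathway GMT.

    A configurable handful of pathways oversamples truly differential
    metabolites so enrichment has signal; unnamed metabolites (UNK ids) are
    simulated but never annotated to pathways.
    """
    rng = stage_rng(cfg.seed, stage)
    n = cfg.n_metabolites
    n_unnamed = int(round(cfg.frac_unnamed * n))
    named = [f"M{i + 1:05d}" for i in range(n - n_unnamed)]
    unnamed = [f"UNK{i + 1:04d}" for i in range(n_unnamed)]
    ids = named + unnamed
    n_case, n_control = cfg.metab_samples_per_group
    sim = _simulate_lognormal(cfg, rng, ids, n_case, n_control,
                              cfg.metab_frac_de, cfg.metab_effect_log2fc,
                              cfg.metab_noise_sd, None, apply_mnar=False)
    truth = sim.truth.set_index("feature_id")
    de_named = [m for m in named if truth.loc[m, "is_de"]]
    other_named = [m for m in named if not truth.loc[m, "is_de"]]
    lo, hi = cfg.pathway_size_range
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    prng = stage_rng(cfg.seed, stage + "_pathways")
    for i in range(cfg.pathway_count):
        size = int(prng.integers(lo, hi + 1))
        size = min(size, len(named))
        enriched = i < cfg.n_enriched_pathways and de_named
        if enriched:
            n_de_members = min(int(round(cfg.enriched_member_frac * size)),
                               len(de_named))
            members = list(prng.choice(de_named, size=n_de_members,
                                       replace=False))
            rest = min(size - n_de_members, len(other_named))
            members += list(prng.choice(other_named, size=rest,
                                        replace=False))
        else:
            members = list(prng.choice(named, size=size, replace=False))
        name = f"PATH_{i + 1:02d}"
        sets[name] = sorted(set(members))
        desc[name] = "enriched" if enriched else "background"
    return sim, GeneSetCollection(sets=sets, descriptions=desc)


def generate_reaction_network(cfg: SimConfig, enzymes: Sequence[str],
                              metabolites: Sequence[str],
                              stage: str = "reactions") -> pd.DataFrame:
    """Bipartite enzyme-metabolite reaction edge table (no enzyme-enzyme or
    metabolite-metabolite edges by construction)."""
    if not enzymes or not metabolites:
        raise SynthIOError("need at least one enzyme and one metabolite")
    overlap = set(enzymes) & set(metabolites)
    if overlap:
        raise SynthIOError(f"ids on both sides break bipartiteness: "
                           f"{sorted(overlap)[:3]}")
    rng = stage_rng(cfg.seed, stage)
    rows = []
    seen = set()
    for r in range(cfg.n_reactions):
        rid = f"R{r + 1:04d}"
        enz = enzymes[int(rng.integers(len(enzymes)))]
        n_met = int(rng.integers(1, min(4, len(metabolites) + 1)))
        mets = rng.choice(len(metabolites), size=n_met, replace=False)
        for mi in mets:
            met = metabolites[int(mi)]
            if (enz, met) in seen:
                continue
            seen.add((enz, met))
            rows.append((enz, met, rid))
    return pd.DataFrame(rows, columns=["enzyme_gene", "metabolite_id",
                                       "reaction_id"])


def generate_dose_response(cfg: SimConfig, stage: str = "dose_response"
                           ) -> dict[str, pd.DataFrame]:
    """Long-format glucose dose-response tables for OCR and ECAR.

    Each subject's curve is a saturating logistic in log10 dose plus a
    subject-level random intercept and per-point noise; the case group is
    shifted by the configured group effect (OCR down, ECAR up in PAH).
    """
    rng = stage_rng(cfg.seed, stage)
    doses = np.asarray(cfg.doses, dtype=float)
    if np.any(np.diff(doses) <= 0):
        raise SynthIOError("doses must be strictly increasing")
    shift_dose = doses[doses > 0].min() if (doses > 0).any() else 1.0
    x = np.log10(doses + shift_dose)
    profile = expit((x - x.mean()) / max(x.std(), 1e-9))  # saturating in dose
    n_case, n_control = cfg.assay_subjects_per_group
    tables = {}
    for measure, base, shift, amp_sign in (
            ("OCR", cfg.ocr_control_mean, cfg.ocr_case_shift, 1.0),
            ("ECAR", cfg.ecar_control_mean, cfg.ecar_case_shift, 1.0)):
        rows = []
        for group, n_subj, label in (("case", n_case, "PAH"),
                                     ("control", n_control, "CTRL")):
            for s in range(n_subj):
                subject = f"{label}_{measure}_{s + 1}"
                level = base + (shift if group == "case" else 0.0)
                level += rng.normal(0.0, cfg.assay_subject_sd)
                resp = (level + amp_sign * 20.0 * profile
                        + rng.normal(0.0, cfg.assay_noise_sd, size=len(doses)))
                for d, r in zip(doses, resp):
                    rows.append((subject, group, d, r))
        tables[measure] = pd.DataFrame(
            rows, columns=["subject_id", "group", "dose", "response"])
    return tables
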