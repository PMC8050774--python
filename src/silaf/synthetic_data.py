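"""Synthetic two-channel (heavy/light) labeled proteomics experiments.

Generates a complete in-silico SILAC/SILAF study — a random proteome,
Lys-C/P digestion, first-order heavy-lysine labeling kinetics, two-condition
fold changes concentrated in a designated functional category (an
OXPHOS-like down-regulation), phosphosites with localization probabilities,
biological and technical replicates, contaminant and decoy rows — together
with a persisted :class:`GroundTruth`, so that every downstream stage of the
pipeline can be scored by parameter recovery.

The labeling model is a single-pool first-order process: the heavy fraction
of a protein with turnover rate ``k`` (per day) after ``t`` days on heavy
food is ``1 - exp(-k t)``.  Two kinetic regimes are provided: a fast
"larval" regime (essentially complete labeling within days) and a slow
"adult" regime in which the proteome-wide mean labeling reaches roughly 45%
after two weeks, with ribosomal proteins labeling markedly faster than
OXPHOS subunits.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .tables_io import (
    AMINO_ACIDS,
    CategoryAnnotation,
    EvidenceRow,
    GeneSet,
    ProteinGroupRow,
    SiteRow,
    write_annotation,
    write_evidence,
    write_gmt,
    write_protein_groups,
    write_sites,
)

# ---------------------------------------------------------------------------
# Lys-C/P digestion
# ---------------------------------------------------------------------------


def lysc_digest(sequence: str, max_missed: int = 0) -> list[tuple[str, int, int]]:
    """In-silico Lys-C/P digestion.

    Cleaves strictly C-terminal of every lysine, *including* before proline
    (the "/P" rule).  Returns ``(peptide, start_1based, n_missed)`` for all
    fully cleaved peptides plus every join of up to ``max_missed`` adjacent
    ones, ordered by start coordinate then missed-cleavage count.

    >>> lysc_digest("MKAK", 0)
    [('MK', 1, 0), ('AK', 3, 0)]
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bad = sorted(set(sequence) - AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residue(s) in sequence: {bad}")
    # fully cleaved fragments: cut after every K
    starts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa == "K":
            starts.append(i + 1)
    bounds = starts + [len(sequence)]
    base = [(sequence[bounds[i]:bounds[i + 1]], bounds[i] + 1)
            for i in range(len(bounds) - 1)]
    out: list[tuple[str, int, int]] = []
    for i in range(len(base)):
        for m in range(min(max_missed, len(base) - 1 - i) + 1):
            pep = "".join(base[j][0] for j in range(i, i + m + 1))
            out.append((pep, base[i][1], m))
    out.sort(key=lambda x: (x[1], x[2]))
    return out


def incorporation_fraction(k: float, t: float) -> float:
    """Heavy fraction ``1 - exp(-k t)`` of a protein pool turning over at
    rate ``k`` (per day) after ``t`` days of pulse labeling."""
    if k <= 0:
        raise ValueError("turnover rate k must be positive")
    if t < 0:
        raise ValueError("time t must be non-negative")
    return -math.expm1(-k * t)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticProtein:
    """True parameters of one simulated protein.

    ``phosphosites`` entries are ``(position, residue, occ_control, occ_kd)``
    with occupancies in (0, 1); the true log2 occupancy change of a site is
    ``log2(occ_kd / occ_control)``.
    """

    protein_id: str
    sequence: str
    abundance: float
    turnover_rate_k: float
    functional_category: str
    true_log2fc: float
    phosphosites: tuple[tuple[int, str, float, float], ...] = ()

    def __post_init__(self) -> None:
        if "K" not in self.sequence:
            raise ValueError(f"{self.protein_id}: sequence must contain >= 1 lysine")
        for pos, res, occ_c, occ_k in self.phosphosites:
            if res not in "STY":
                raise ValueError(f"{self.protein_id}: phospho residue {res!r} not in STY")
            if not 1 <= pos <= len(self.sequence) or self.sequence[pos - 1] != res:
                raise ValueError(
                    f"{self.protein_id}: phosphosite {res}{pos} does not match sequence")
            if not (0 < occ_c < 1 and 0 < occ_k < 1):
                raise ValueError(f"{self.protein_id}: occupancies must lie in (0, 1)")


@dataclass(frozen=True)
class NoiseModel:
    """Noise and missingness parameters of the simulated measurement.

    Sigmas are on the log2 scale.  Missingness is missing-not-at-random:
    each channel intensity is dropped with logistic probability
    ``max_rate / (1 + exp(slope * (log2 I - mid)))``, i.e. preferentially at
    low intensity.
    """

    sigma_peptide_log2: float = 0.25   # per peptide x replicate ratio noise
    sigma_bio_log2: float = 0.05       # shared per protein x biological replicate
    sigma_intensity_log2: float = 1.0  # total-intensity jitter per observation
    sigma_timecourse_log2: float = 0.02  # per-channel noise in time-course mode
    missing_max_rate: float = 0.3
    missing_mid_log2: float = 16.0
    missing_slope: float = 1.0
    loc_prob_confident_fraction: float = 0.8

    @staticmethod
    def noise_free() -> "NoiseModel":
        return NoiseModel(sigma_peptide_log2=0.0, sigma_bio_log2=0.0,
                          sigma_intensity_log2=0.0, sigma_timecourse_log2=0.0,
                          missing_max_rate=0.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Replicate and acquisition design of the simulated experiment."""

    mode: str = "comparison"           # "comparison" | "timecourse"
    n_bio: int = 4
    n_tech: int = 2
    timepoints_days: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0)
    max_missed_cleavages: int = 2
    peptide_length_range: tuple[int, int] = (7, 40)
    max_peptides_per_protein: int = 10
    mean_peptides_per_protein: float = 5.0
    contaminant_rate: float = 0.02
    decoy_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.mode not in ("comparison", "timecourse"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("replicate counts must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to regenerate and score a synthetic experiment.

    Fully determines the emitted tables: the same ground truth (including
    ``rng_seed``) always yields byte-identical files.
    """

    proteins: tuple[SyntheticProtein, ...]
    design: ExperimentDesign = ExperimentDesign()
    noise: NoiseModel = NoiseModel()
    rng_seed: int = 0

    def protein(self, protein_id: str) -> SyntheticProtein:
        return {p.protein_id: p for p in self.proteins}[protein_id]

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rng_seed": self.rng_seed,
            "design": dataclasses.asdict(self.design),
            "noise": dataclasses.asdict(self.noise),
            "proteins": [dataclasses.asdict(p) for p in self.proteins],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @staticmethod
    def from_json(path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        proteins = tuple(
            SyntheticProtein(
                protein_id=p["protein_id"], sequence=p["sequence"],
                abundance=p["abundance"], turnover_rate_k=p["turnover_rate_k"],
                functional_category=p["functional_category"],
                true_log2fc=p["true_log2fc"],
                phosphosites=tuple(tuple(s) for s in p["phosphosites"]),
            )
            for p in payload["proteins"]
        )
        design = ExperimentDesign(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in payload["design"].items()})
        return GroundTruth(proteins=proteins, design=design,
                           noise=NoiseModel(**payload["noise"]),
                           rng_seed=payload["rng_seed"])


# Per-category kinetic medians (per day) for the slow "adult" regime,
# calibrated so that after 14 labeling days ribosomal proteins sit near 52%
# incorporation, OXPHOS near 18%, and the bulk proteome near 45%.
_ADULT_K_MEDIANS = {
    "OXPHOS": 0.01435,
    "Ribosome": 0.0522,
    "default": 0.0427,
}
# Fast "larval" regime: median incorporation >= 97% by day 4.
_LARVAL_K_SCALE = 20.0

_CATEGORIES = ("OXPHOS", "Ribosome", "Glycolysis", "TCA cycle", "Proteasome")
_MITO_CATEGORIES = {"OXPHOS", "TCA cycle"}
#: amino-acid sampling weights; lysine at ~7% gives ~14-residue tryptic-like peptides
_AA_ALPHABET = "ACDEFGHILMNPQRSTVWYK"


def make_ground_truth(
    n_proteins: int = 1000,
    design: ExperimentDesign = ExperimentDesign(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    regulated_category: str = "OXPHOS",
    regulated_log2fc: float = -1.0,
    category_size: int = 50,
    kinetic_regime: str = "adult",
    mean_phosphosites: float = 2.0,
    site_regulated_fraction: float = 0.2,
    site_occupancy_shift_log2: float = 1.0,
) -> GroundTruth:
    """Draw a random proteome with category structure and true effects.

    The first ``category_size`` proteins of each named category carry that
    category's kinetics; ``regulated_category`` additionally carries a true
    condition effect centered on ``regulated_log2fc`` (all other proteins
    have a true log2 fold change of exactly 0).  A fraction of phosphosites
    is regulated with a +/- ``site_occupancy_shift_log2`` occupancy change.
    """
    if n_proteins < len(_CATEGORIES) * category_size:
        category_size = max(1, n_proteins // (2 * len(_CATEGORIES)))
    rng = np.random.default_rng(seed)
    aa = np.array(list(_AA_ALPHABET))
    weights = np.full(len(aa), (1 - 0.07) / (len(aa) - 1))
    weights[-1] = 0.07  # lysine
    proteins = []
    for i in range(n_proteins):
        category = (_CATEGORIES[i // category_size]
                    if i < len(_CATEGORIES) * category_size else "background")
        length = int(np.clip(rng.lognormal(math.log(350), 0.35), 60, 2000))
        seq = "".join(rng.choice(aa, size=length, p=weights))
        if "K" not in seq:
            seq = seq[:-1] + "K"
        abundance = float(rng.lognormal(math.log(1e7), 1.2))
        k_med = _ADULT_K_MEDIANS.get(category, _ADULT_K_MEDIANS["default"])
        if kinetic_regime == "larval":
            k_med *= _LARVAL_K_SCALE
        k = float(k_med * rng.lognormal(0.0, 0.35))
        if category == regulated_category:
            log2fc = float(rng.normal(regulated_log2fc, 0.2))
        else:
            log2fc = 0.0
        # phosphosites on S/T/Y positions of the sequence
        sty = [j + 1 for j, r in enumerate(seq) if r in "STY"]
        n_sites = min(rng.poisson(mean_phosphosites), len(sty))
        positions = sorted(rng.choice(sty, size=n_sites, replace=False)) if n_sites else []
        sites = []
        for pos in positions:
            occ_c = float(rng.uniform(0.1, 0.8))
            if rng.random() < site_regulated_fraction:
                delta = site_occupancy_shift_log2 * (1 if rng.random() < 0.5 else -1)
                occ_k = float(np.clip(occ_c * 2.0 ** delta, 0.02, 0.98))
            else:
                occ_k = occ_c
            sites.append((int(pos), seq[pos - 1], occ_c, occ_k))
        proteins.append(SyntheticProtein(
            protein_id=f"P{i:04d}", sequence=seq, abundance=abundance,
            turnover_rate_k=k, functional_category=category,
            true_log2fc=log2fc, phosphosites=tuple(sites)))
    return GroundTruth(proteins=tuple(proteins), design=design, noise=noise,
                       rng_seed=seed)


def true_occupancy_change(protein: SyntheticProtein, position: int) -> float:
    """True log2 occupancy change (knockdown vs control) of one site."""
    for pos, _res, occ_c, occ_k in protein.phosphosites:
        if pos == position:
            return math.log2(occ_k / occ_c)
    raise KeyError(f"no phosphosite at position {position} of {protein.protein_id}")


def annotation_from_truth(gt: GroundTruth) -> CategoryAnnotation:
    mapping = {
        p.protein_id: (p.functional_category in _MITO_CATEGORIES, p.functional_category)
        for p in gt.proteins if p.functional_category != "background"
    }
    return CategoryAnnotation(mapping)


def gene_sets_from_truth(gt: GroundTruth) -> list[GeneSet]:
    by_cat: dict[str, set[str]] = {}
    for p in gt.proteins:
        if p.functional_category != "background":
            by_cat.setdefault(p.functional_category, set()).add(p.protein_id)
    return [GeneSet(set_id=cat, description=f"synthetic {cat} category",
                    members=frozenset(ids))
            for cat, ids in sorted(by_cat.items())]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _detectable_peptides(p: SyntheticProtein, design: ExperimentDesign,
                         rng: np.random.Generator) -> list[tuple[str, int, int, float]]:
    """Digest and pick the observable peptides with per-peptide yields.

    Yield emulates MS observability (ionization, recovery) as a fixed
    log-normal factor per peptide; missed-cleavage forms get a 0.3 penalty.
    """
    lo, hi = design.peptide_length_range
    peps = [t for t in lysc_digest(p.sequence, design.max_missed_cleavages)
            if lo <= len(t[0]) <= hi]
    # the number of observed peptides per protein is highly dispersed in real
    # data (many one-hit proteins); draw it rather than using a fixed cap
    n_detect = int(min(len(peps), design.max_peptides_per_protein,
                       1 + rng.poisson(max(design.mean_peptides_per_protein - 1, 0))))
    if len(peps) > n_detect:
        idx = sorted(rng.choice(len(peps), size=n_detect, replace=False))
        peps = [peps[i] for i in idx]
    out = []
    for seq, start, miss in peps:
        y = float(np.exp2(rng.normal(-3.0, 0.8)))
        if miss > 0:
            y *= 0.3
        out.append((seq, start, miss, y))
    return out


def _missing(intensity: float, noise: NoiseModel, rng: np.random.Generator) -> bool:
    if noise.missing_max_rate <= 0 or intensity <= 0:
        return False
    z = noise.missing_slope * (math.log2(intensity) - noise.missing_mid_log2)
    prob = noise.missing_max_rate / (1.0 + math.exp(z))
    return bool(rng.random() < prob)


def _loc_probability(noise: NoiseModel, rng: np.random.Generator) -> float:
    """Two-component localization-probability mixture.

    A configured fraction of sites is "confident" (drawn above 0.75), the
    rest ambiguous (drawn at or below 0.75), so the strict > 0.75 filter
    retains exactly a Binomial(n, confident_fraction) share.
    """
    if rng.random() < noise.loc_prob_confident_fraction:
        return float(0.75 + 0.25 * rng.beta(5.0, 1.0))
    return float(0.75 * rng.beta(2.0, 2.0))


def simulate_tables(
    gt: GroundTruth,
) -> tuple[list[EvidenceRow], list[ProteinGroupRow], list[SiteRow]]:
    """Simulate the evidence, protein-groups, and sites tables in memory.

    Comparison mode encodes the condition contrast in each peptide's H/L
    ratio (heavy = knockdown/treatment, light = control); time-course mode
    sets the heavy share of each peptide's intensity to the protein's
    labeling fraction ``1 - exp(-k t)``.  Deterministic given the ground
    truth (the RNG is seeded from ``gt.rng_seed``).
    """
    design, noise = gt.design, gt.noise
    rng = np.random.default_rng(gt.rng_seed)
    evidence: list[EvidenceRow] = []
    pgroups: list[ProteinGroupRow] = []
    sites: list[SiteRow] = []

    for p in gt.proteins:
        peps = _detectable_peptides(p, design, rng)
        tot_h = tot_l = 0.0
        if design.mode == "comparison":
            bio_dev = rng.normal(0.0, noise.sigma_bio_log2, size=design.n_bio) \
                if noise.sigma_bio_log2 > 0 else np.zeros(design.n_bio)
            for b in range(1, design.n_bio + 1):
                for t in range(1, design.n_tech + 1):
                    run = f"run_b{b}_t{t}"
                    for seq, _start, _miss, y in peps:
                        inten = p.abundance * y * float(np.exp2(
                            rng.normal(0.0, noise.sigma_intensity_log2))) \
                            if noise.sigma_intensity_log2 > 0 else p.abundance * y
                        log2r = p.true_log2fc + bio_dev[b - 1]
                        if noise.sigma_peptide_log2 > 0:
                            log2r += rng.normal(0.0, noise.sigma_peptide_log2)
                        r = 2.0 ** log2r
                        h = inten * r / (1.0 + r)
                        light = inten / (1.0 + r)
                        h_out = None if _missing(h, noise, rng) else h
                        l_out = None if _missing(light, noise, rng) else light
                        if h_out is None and l_out is None:
                            continue
                        tot_h += h_out or 0.0
                        tot_l += l_out or 0.0
                        evidence.append(EvidenceRow(
                            peptide_sequence=seq, charge=int(rng.integers(2, 5)),
                            intensity_heavy=h_out, intensity_light=l_out,
                            protein_group_id=p.protein_id, raw_file=run,
                            replicate_bio=b, replicate_tech=t))
            # phosphosites: site H/L carries protein fold change x occupancy ratio
            for pos, res, occ_c, occ_k in p.phosphosites:
                loc = _loc_probability(noise, rng)
                # per-site noise scale: site-level measurement error is
                # heterogeneous in real data (intensity, peptide chemistry)
                noise_scale = float(rng.lognormal(0.0, 0.4)) \
                    if noise.sigma_peptide_log2 > 0 else 1.0
                ratios: dict[str, float] = {}
                site_h = site_l = 0.0
                for b in range(1, design.n_bio + 1):
                    for t in range(1, design.n_tech + 1):
                        log2r = (p.true_log2fc + math.log2(occ_k / occ_c)
                                 + bio_dev[b - 1])
                        if noise.sigma_peptide_log2 > 0:
                            log2r += rng.normal(
                                0.0, noise.sigma_peptide_log2 * noise_scale)
                        inten = p.abundance * 0.05
                        if noise.sigma_intensity_log2 > 0:
                            inten *= float(np.exp2(rng.normal(0.0, noise.sigma_intensity_log2)))
                        if _missing(inten, noise, rng):
                            continue
                        r = 2.0 ** log2r
                        ratios[f"b{b}_t{t}"] = r
                        site_h += inten * r / (1.0 + r)
                        site_l += inten / (1.0 + r)
                sites.append(SiteRow(
                    protein_group_id=p.protein_id, position_in_protein=pos,
                    residue=res, localization_probability=loc,
                    ratio_hl_per_replicate=ratios,
                    intensity_heavy=site_h or None, intensity_light=site_l or None))
        else:  # timecourse
            frac_by_t = {t: incorporation_fraction(p.turnover_rate_k, t)
                         if t > 0 else 0.0 for t in design.timepoints_days}
            for t_days in design.timepoints_days:
                f = frac_by_t[t_days]
                for b in range(1, design.n_bio + 1):
                    run = f"tc_d{t_days:g}_b{b}"
                    for seq, _start, _miss, y in peps:
                        inten = p.abundance * y
                        if noise.sigma_intensity_log2 > 0:
                            inten *= float(np.exp2(rng.normal(0.0, noise.sigma_intensity_log2)))
                        eh = el = 1.0
                        if noise.sigma_timecourse_log2 > 0:
                            eh = float(np.exp2(rng.normal(0.0, noise.sigma_timecourse_log2)))
                            el = float(np.exp2(rng.normal(0.0, noise.sigma_timecourse_log2)))
                        h = inten * f * eh
                        light = inten * (1.0 - f) * el
                        tot_h += h
                        tot_l += light
                        evidence.append(EvidenceRow(
                            peptide_sequence=seq, charge=int(rng.integers(2, 5)),
                            intensity_heavy=h, intensity_light=light,
                            protein_group_id=p.protein_id, raw_file=run,
                            replicate_bio=b, timepoint_days=float(t_days)))
        pgroups.append(ProteinGroupRow(
            protein_group_id=p.protein_id, member_protein_ids=(p.protein_id,),
            ratio_hl_normalized=2.0 ** p.true_log2fc,
            intensity_heavy=tot_h or None, intensity_light=tot_l or None))

    # contaminant / decoy injection (flagged rows exercising the filters)
    n_cont = int(round(design.contaminant_rate * len(evidence)))
    n_decoy = int(round(design.decoy_rate * len(evidence)))
    junk_seqs = ["".join(rng.choice(list("ACDEFGHILMNPQRSTVWY"), size=12)) + "K"
                 for _ in range(8)]
    for kind, count in (("CON", n_cont), ("REV", n_decoy)):
        n_groups = max(1, count // 50) if count else 0
        for g in range(n_groups):
            gid = f"{kind}__{g:03d}"
            pgroups.append(ProteinGroupRow(
                protein_group_id=gid, member_protein_ids=(gid,),
                flag_contaminant=kind == "CON", flag_reverse=kind == "REV"))
        for j in range(count):
            gid = f"{kind}__{j % max(1, n_groups):03d}"
            b = int(rng.integers(1, design.n_bio + 1))
            t = int(rng.integers(1, design.n_tech + 1)) if design.mode == "comparison" else 1
            inten = float(rng.lognormal(math.log(1e6), 1.0))
            r = float(rng.lognormal(0.0, 0.5))
            evidence.append(EvidenceRow(
                peptide_sequence=str(rng.choice(junk_seqs)),
                charge=int(rng.integers(2, 5)),
                intensity_heavy=inten * r / (1 + r), intensity_light=inten / (1 + r),
                protein_group_id=gid,
                raw_file=f"run_b{b}_t{t}" if design.mode == "comparison" else "tc_junk",
                replicate_bio=b, replicate_tech=t,
                timepoint_days=0.0 if design.mode == "timecourse" else None))
    return evidence, pgroups, sites


def simulate_experiment(gt: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and persist a full experiment into ``out_dir``.

    Writes ``evidence.txt``, ``proteinGroups.txt``, ``sites.txt`` (comparison
    mode), ``annotation.tsv``, ``categories.gmt`` and ``ground_truth.json``.
    Identical ground truth -> byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    evidence, pgroups, sites = simulate_tables(gt)
    paths = {
        "evidence": out / "evidence.txt",
        "protein_groups": out / "proteinGroups.txt",
        "annotation": out / "annotation.tsv",
        "gene_sets": out / "categories.gmt",
        "ground_truth": out / "ground_truth.json",
    }
    write_evidence(evidence, paths["evidence"])
    write_protein_groups(pgroups, paths["protein_groups"])
    if sites:
        paths["sites"] = out / "sites.txt"
        write_sites(sites, paths["sites"])
    write_annotation(annotation_from_truth(gt), paths["annotation"])
    write_gmt(gene_sets_from_truth(gt), paths["gene_sets"])
    gt.to_json(paths["ground_truth"])
    return paths
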