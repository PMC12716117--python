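"""Synthetic multi-acquisition PSM data emulating a paired islet study.

The generator emulates the statistical structure of a six-donor,
two-condition (control vs cytokine-treated), FAIMS three-CV-channel
top-down LC-MS experiment: proteoforms are truncation products of packaged
prohormone precursor sequences (biased toward dibasic cleavage sites), each
acquisition carries its own ppm mass bias and monotone cubic RT warp,
intensities follow a log2-normal abundance model with donor effects and
region-wise treatment fold changes, observations go missing with
probability decreasing in abundance, and decoy PSMs with null E-values are
appended.  A :class:`TruthManifest` records every latent quantity so each
pipeline stage can be checked against ground truth.

All randomness flows from one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .core import SampleDesign, format_proteoform_name, ProteoformKey
from .ingest import CANONICAL_COLUMNS, encode_mod_shifts, write_psm_table
from .masses import theoretical_mass
from .regions import RegionMap, load_region_map

GENE_ACCESSIONS = {
    "INS": "P01308", "GCG": "P01275", "SST": "P61278",
    "IAPP": "P10997", "PPY": "P01298", "CHGA": "CHGA_SYNTH",
}

#: simple variable modifications available to the generator (delta Da)
_SIM_MODS = [("Oxidation", 15.99491), ("Phospho", 79.96632),
             ("Acetyl", 42.01057)]


def load_precursors() -> dict:
    """Packaged precursor sequences, gene -> sequence.

    INS/GCG/SST/IAPP/PPY are the real UniProt precursors; CHGA is a
    synthetic stand-in with authentic length and processing-site layout
    (see data/chga_synthetic.fasta).
    """
    seqs: dict = {}
    for fname in ("precursors.fasta", "chga_synthetic.fasta"):
        text = (resources.files("proformquant.data") / fname).read_text()
        gene = None
        for line in text.splitlines():
            if line.startswith(">"):
                gene = line[1:].split()[0]
                seqs[gene] = []
            elif gene:
                seqs[gene].append(line.strip())
    return {g: "".join(parts) for g, parts in seqs.items()}


DEFAULT_REGION_EFFECTS = {
    "GCG": {"major proglucagon fragment": 1.5, "GRPP": -1.5},
    "CHGA": {"LF-19/catestatin": -1.5, "vasostatin-1/2": 1.5},
}


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator."""

    seed: int = 1
    n_donors: int = 6
    cv_channels: tuple = ("-55", "-45", "-35")
    genes: tuple = tuple(sorted(GENE_ACCESSIONS))
    proteoforms_per_gene: int = 40
    mod_probability: float = 0.3
    # mass model
    ppm_bias_sd: float = 3.0
    ppm_noise_sd: float = 2.0
    # retention time model (minutes)
    rt_range: tuple = (15.0, 95.0)
    rt_noise_sd_min: float = 0.3
    identity_warp: bool = False
    warp_intercept_range: tuple = (-2.0, 2.0)
    warp_linear_range: tuple = (0.95, 1.05)
    warp_quad_range: tuple = (-8e-4, 8e-4)
    warp_cubic_range: tuple = (-3e-6, 3e-6)
    # abundance model (log2 scale)
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    donor_sd: float = 0.5
    residual_sd: float = 0.3
    region_effects: dict = field(
        default_factory=lambda: {g: dict(v)
                                 for g, v in DEFAULT_REGION_EFFECTS.items()})
    # missingness: P(observed) = sigmoid(intercept + slope*(log2a - baseline))
    missing_intercept: float = 1.4
    missing_slope: float = 0.6
    #: fraction of proteoforms induced by treatment (never present in
    #: control samples), emulating condition-unique observations
    treatment_only_fraction: float = 0.03
    # PSM layer
    decoy_fraction: float = 0.05
    extra_psm_rate: float = 0.3

    def validate(self) -> None:
        for name in ("ppm_bias_sd", "ppm_noise_sd", "rt_noise_sd_min",
                     "baseline_sd", "donor_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.decoy_fraction < 1):
            raise ValueError("decoy_fraction must be in [0, 1)")
        if not (0 <= self.mod_probability <= 1):
            raise ValueError("mod_probability must be in [0, 1]")


def null_config(seed: int = 1, **kw) -> SimConfig:
    """All treatment effects zero (type-I / specificity scenario)."""
    return SimConfig(seed=seed, region_effects={}, **kw)


def noiseless_config(seed: int = 1, **kw) -> SimConfig:
    """No mass/RT noise and identity warps; per-dataset ppm biases remain."""
    return SimConfig(seed=seed, ppm_noise_sd=0.0, rt_noise_sd_min=0.0,
                     identity_warp=True, residual_sd=0.0, **kw)


SCENARIOS = {"default": SimConfig, "null": null_config,
             "noiseless": noiseless_config}


def _dibasic_sites(seq: str) -> list:
    """1-based positions i such that residues (i, i+1) are both K/R."""
    return [i + 1 for i in range(len(seq) - 1)
            if seq[i] in "KR" and seq[i + 1] in "KR"]


def _sample_proteoforms(cfg: SimConfig, rng: np.random.Generator,
                        sequences: dict, region_map: RegionMap) -> pd.DataFrame:
    rows = []
    seen = set()
    for gene in cfg.genes:
        seq = sequences[gene]
        acc = GENE_ACCESSIONS.get(gene, gene)
        sites = _dibasic_sites(seq)
        # cleavage after a dibasic pair -> product starts 2 after the site;
        # product ends just before the site.  Known processing-region
        # boundaries are added so canonical products are well represented.
        cand_starts = {s + 2 for s in sites if s + 2 <= len(seq)}
        cand_ends = {s - 1 for s in sites if s - 1 >= 1}
        for reg in region_map.regions_of(gene):
            cand_starts.add(reg.first_aa)
            if reg.last_aa <= len(seq):
                cand_ends.add(reg.last_aa)
        cand_starts = sorted(cand_starts)
        cand_ends = sorted(cand_ends)
        made = 0
        attempts = 0
        while made < cfg.proteoforms_per_gene and attempts < 50 * cfg.proteoforms_per_gene:
            attempts += 1
            if cand_starts and rng.random() < 0.7:
                first = int(rng.choice(cand_starts))
            else:
                first = int(rng.integers(1, len(seq)))
            if cand_ends and rng.random() < 0.7:
                last = int(rng.choice(cand_ends))
            else:
                last = int(rng.integers(first, len(seq) + 1))
            if not (1 <= first < last <= len(seq)) or last - first + 1 < 8:
                continue
            mods = []
            if rng.random() < cfg.mod_probability:
                name, delta = _SIM_MODS[int(rng.integers(len(_SIM_MODS)))]
                a = int(rng.integers(first, last + 1))
                b = min(last, a + int(rng.integers(0, 4)))
                mods = [(delta, f"{a}-{b}")]
            key = ProteoformKey(gene, acc, first, last,
                                tuple((round(d, 2), loc) for d, loc in mods))
            label = format_proteoform_name(key)
            # labels index the truth tables, so keep them unique
            if label in seen:
                continue
            seen.add(label)
            theo = theoretical_mass(seq[first - 1:last],
                                    [d for d, _ in mods])
            effect = 0.0
            for region, lfc in cfg.region_effects.get(gene, {}).items():
                reg = region_map.get(gene, region)
                if reg.contains(first, last):
                    effect += lfc
            rows.append({
                "pf_id": len(rows), "gene": gene, "accession": acc,
                "first_aa": first, "last_aa": last,
                "mod_shifts": encode_mod_shifts(mods),
                "label": label,
                "theo_mass": theo,
                "true_rt": float(rng.uniform(*cfg.rt_range)),
                "injected_lfc": effect,
            })
            made += 1
    return pd.DataFrame(rows)


def _draw_warp(cfg: SimConfig, rng: np.random.Generator) -> tuple:
    if cfg.identity_warp:
        return (0.0, 1.0, 0.0, 0.0)
    for _ in range(100):
        c = (float(rng.uniform(*cfg.warp_intercept_range)),
             float(rng.uniform(*cfg.warp_linear_range)),
             float(rng.uniform(*cfg.warp_quad_range)),
             float(rng.uniform(*cfg.warp_cubic_range)))
        t = np.linspace(0.0, 120.0, 241)
        deriv = c[1] + 2 * c[2] * t + 3 * c[3] * t ** 2
        if np.all(deriv > 0):
            return c
    raise ValueError("could not draw a monotone warp; narrow the ranges")


def warp_apply(coeffs: tuple, t: np.ndarray) -> np.ndarray:
    c0, c1, c2, c3 = coeffs
    t = np.asarray(t, dtype=float)
    return c0 + c1 * t + c2 * t ** 2 + c3 * t ** 3


@dataclass
class TruthManifest:
    """Ground truth sufficient to recompute every expected pipeline output."""

    config: SimConfig
    proteoforms: pd.DataFrame      # identity, theoretical mass, true RT, lfc
    datasets: pd.DataFrame         # dataset_id, donor, condition, bias, warp
    abundance: pd.DataFrame        # true log2 abundance, pf x sample
    presence: pd.DataFrame         # observed mask, pf x sample

    def warp_of(self, dataset_id: str):
        row = self.datasets.set_index("dataset_id").loc[dataset_id]
        return (row["warp_c0"], row["warp_c1"], row["warp_c2"], row["warp_c3"])

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "proteoforms": self.proteoforms.to_dict(orient="list"),
            "datasets": self.datasets.to_dict(orient="list"),
            "abundance": {
                "index": list(self.abundance.index),
                "columns": list(self.abundance.columns),
                "values": [[None if not np.isfinite(v) else v for v in row]
                           for row in self.abundance.to_numpy()],
            },
            "presence": {
                "index": list(self.presence.index),
                "columns": list(self.presence.columns),
                "values": self.presence.to_numpy().astype(int).tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class SimResult:
    tables: dict                  # dataset_id -> canonical PSM frame
    design: SampleDesign
    manifest: TruthManifest

    def combined_frame(self) -> pd.DataFrame:
        return pd.concat(self.tables.values(), ignore_index=True)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for ds, frame in self.tables.items():
            write_psm_table(frame, outdir / f"{ds}.psms.tsv")
        self.design.to_csv(outdir / "design.csv")
        self.manifest.to_json(outdir / "manifest.json")


def simulate(config: SimConfig, region_map: RegionMap | None = None) -> SimResult:
    """Generate PSM tables, a design table, and the truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if region_map is None:
        region_map = load_region_map()
    sequences = load_precursors()
    pf = _sample_proteoforms(config, rng, sequences, region_map)
    n_pf = len(pf)

    donors = [f"D{i + 1}" for i in range(config.n_donors)]
    design_rows = [{"sample_id": f"{d}_{c}", "donor_id": d, "condition": c}
                   for d in donors for c in ("control", "treated")]
    design = SampleDesign(pd.DataFrame(design_rows))
    sample_ids = design.sample_ids

    ds_rows = []
    for sid in sample_ids:
        warp = _draw_warp(config, rng)
        ds_rows.append({
            "dataset_id": sid,
            "donor_id": sid.rsplit("_", 1)[0],
            "condition": sid.rsplit("_", 1)[1],
            "ppm_bias": float(rng.normal(0.0, config.ppm_bias_sd)),
            "warp_c0": warp[0], "warp_c1": warp[1],
            "warp_c2": warp[2], "warp_c3": warp[3],
        })
    datasets = pd.DataFrame(ds_rows)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_pf)
    donor_eff = rng.normal(0.0, config.donor_sd, (n_pf, config.n_donors))
    abundance = pd.DataFrame(index=pf["label"], columns=sample_ids,
                             dtype=float)
    for j, sid in enumerate(sample_ids):
        d_idx = donors.index(sid.rsplit("_", 1)[0])
        treated = sid.endswith("treated")
        a = (baseline + donor_eff[:, d_idx]
             + (pf["injected_lfc"].to_numpy() if treated else 0.0)
             + rng.normal(0.0, config.residual_sd, n_pf))
        abundance[sid] = a
    logit = (config.missing_intercept
             + config.missing_slope * (abundance - config.baseline_mean))
    p_obs = 1.0 / (1.0 + np.exp(-logit))
    presence = pd.DataFrame(rng.random((n_pf, len(sample_ids))) < p_obs,
                            index=pf["label"], columns=sample_ids)
    n_unique = int(round(config.treatment_only_fraction * n_pf))
    unique_idx = (rng.choice(n_pf, size=n_unique, replace=False)
                  if n_unique else np.array([], dtype=int))
    treatment_only = np.zeros(n_pf, dtype=bool)
    treatment_only[unique_idx] = True
    pf["treatment_only"] = treatment_only
    control_cols = [s for s in sample_ids if s.endswith("control")]
    presence.loc[presence.index[unique_idx], control_cols] = False

    n_cv = len(config.cv_channels)
    presence_np = presence.to_numpy()
    abundance_np = abundance.to_numpy()
    col_of = {sid: j for j, sid in enumerate(sample_ids)}
    tables = {}
    for row in datasets.itertuples(index=False):
        sid = row.dataset_id
        j = col_of[sid]
        warp = (row.warp_c0, row.warp_c1, row.warp_c2, row.warp_c3)
        recs = []
        scan = 0
        for i in range(n_pf):
            if not presence_np[i, j]:
                continue
            total = 2.0 ** abundance_np[i, j]
            weights = rng.dirichlet(np.full(n_cv, 2.0))
            p = pf.iloc[i]
            for ci, cv in enumerate(config.cv_channels):
                n_psm = 1 + rng.poisson(config.extra_psm_rate)
                for _ in range(n_psm):
                    scan += 1
                    ppm = row.ppm_bias + rng.normal(0.0, config.ppm_noise_sd)
                    recs.append({
                        "dataset_id": sid, "scan": scan,
                        "rt_min": max(0.0, float(
                            warp_apply(warp, p["true_rt"])
                            + rng.normal(0.0, config.rt_noise_sd_min))),
                        "mass_da": p["theo_mass"] * (1 + ppm * 1e-6),
                        "accession": p["accession"], "gene": p["gene"],
                        "first_aa": int(p["first_aa"]),
                        "last_aa": int(p["last_aa"]),
                        "mod_shifts": p["mod_shifts"],
                        "evalue": float(
                            10.0 ** -(1.0 + rng.gamma(2.0, 1.5))),
                        "is_decoy": False,
                        "intensity": float(total * weights[ci]),
                        "cv_volts": str(cv),
                    })
        n_targets = len(recs)
        n_decoys = int(round(n_targets * config.decoy_fraction
                             / max(1e-9, 1 - config.decoy_fraction)))
        for k in range(n_decoys):
            scan += 1
            recs.append({
                "dataset_id": sid, "scan": scan,
                "rt_min": float(rng.uniform(5.0, 110.0)),
                "mass_da": float(rng.uniform(2000.0, 20000.0)),
                "accession": f"DECOY_SYN{k}", "gene": "",
                "first_aa": 1, "last_aa": 1, "mod_shifts": "",
                "evalue": float(rng.uniform(0.0, 1.0)),
                "is_decoy": True, "intensity": np.nan,
                "cv_volts": str(config.cv_channels[
                    int(rng.integers(n_cv))]),
            })
        tables[sid] = pd.DataFrame(recs, columns=CANONICAL_COLUMNS)

    manifest = TruthManifest(config=config, proteoforms=pf,
                             datasets=datasets, abundance=abundance,
                             presence=presence)
    return SimResult(tables=tables, design=design, manifest=manifest)


# ---------------------------------------------------------------------------
# Oracle recomputation from the manifest


def expected_outputs(manifest: TruthManifest) -> dict:
    """Deterministic ground-truth targets for checking pipeline output."""
    pf = manifest.proteoforms
    presence = manifest.presence
    design_frame = manifest.datasets
    donors = sorted(design_frame["donor_id"].unique())
    control_ids = {d: f"{d}_control" for d in donors}
    treated_ids = {d: f"{d}_treated" for d in donors}
    both = pd.DataFrame(
        {d: presence[control_ids[d]] & presence[treated_ids[d]]
         for d in donors})
    n_pairs = both.sum(axis=1)
    quantifiable = list(presence.index[n_pairs >= 2])

    n_control = int((design_frame["condition"] == "control").sum())
    n_treated = int((design_frame["condition"] == "treated").sum())
    n_total = n_control + n_treated
    presence_p = {}
    for label, row in presence.iterrows():
        obs_c = int(row[[c for c in presence.columns
                         if c.endswith("control")]].sum())
        obs_t = int(row[[c for c in presence.columns
                         if c.endswith("treated")]].sum())
        k = obs_c + obs_t
        if k == 0 or (obs_c > 0 and obs_t > 0):
            continue
        n_g = n_control if obs_c else n_treated
        presence_p[label] = float(special.comb(n_g, k, exact=True)
                                  / special.comb(n_total, k, exact=True))

    return {
        "n_proteoforms": int(len(pf)),
        "n_observed": int((presence.sum(axis=1) > 0).sum()),
        "quantifiable": quantifiable,
        "expected_lfc": dict(zip(pf["label"], pf["injected_lfc"])),
        "presence_probability": presence_p,
    }
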