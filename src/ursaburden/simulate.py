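"""Synthetic case-control exome cohorts with known gene-set enrichments.

The generator emulates the statistical structure the burden analysis assumes:
ultra-rare, singleton-dominated allele-count spectra; annotation scores drawn
conditionally on an intended variant class so every class has clean positives
and negatives; a strong case-control sex imbalance; control sub-cohorts
(capture-kit batches); principal-component noise; and configurable per-gene-set
enrichment odds ratios, including the all-null case used for calibration.

Carrier model: for every sample, gene and variant *profile* an independent
Bernoulli draw decides whether the sample carries a qualifying variant of that
profile in that gene; for case samples the logit of the carrier probability is
shifted by ln(odds ratio) in spiked (gene set, class) cells.  Because the 13
analysis classes overlap (MPC 2 within MPC 1, CCR 80 within MPC 1 and
MTR ClinVar, paralog tiers, All functional = PTV + in-frame + damaging
missense), the configured ``baseline_qv_rate`` — the *realised* expected QV
count per sample per class per 1,000 genes — is converted internally to
disjoint profile rates by subtracting nested contributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .collapse import GeneSet
from .errors import ConfigurationError
from .qv import CLASS_NAMES, PTV_CONSEQUENCES, VARIANT_COLUMNS

logger = logging.getLogger(__name__)

#: realised expected QVs per sample per class per 1,000 genes
DEFAULT_QV_RATES: dict[str, float] = {
    "Benign missense": 2.0,
    "Damaging missense": 1.5,
    "PTV": 0.6,
    "All functional": 2.4,
    "MPC 1": 1.5,
    "MPC 2": 0.5,
    "MTR ClinVar": 1.5,
    "MTR De Novo": 0.5,
    "CCR 80": 0.4,
    "Paralog non-conserved": 1.5,
    "Paralog conserved": 1.2,
    "Paralog highly conserved": 0.4,
    "Synonymous": 3.0,
}

#: disjoint generation profiles, in fixed draw order
PROFILES = (
    "Benign missense", "Damaging missense", "PTV", "_inframe",
    "MPC 1", "MPC 2", "MTR ClinVar", "MTR De Novo", "CCR 80",
    "Paralog non-conserved", "Paralog conserved", "Paralog highly conserved",
    "Synonymous",
)

#: which profiles realise into each analysis class
CLASS_TO_PROFILES: dict[str, tuple[str, ...]] = {
    "Benign missense": ("Benign missense",),
    "Damaging missense": ("Damaging missense",),
    "PTV": ("PTV",),
    "All functional": ("PTV", "_inframe", "Damaging missense"),
    "MPC 1": ("MPC 1", "MPC 2", "CCR 80"),
    "MPC 2": ("MPC 2",),
    "MTR ClinVar": ("MTR ClinVar", "MTR De Novo", "CCR 80"),
    "MTR De Novo": ("MTR De Novo",),
    "CCR 80": ("CCR 80",),
    "Paralog non-conserved": ("Paralog non-conserved",),
    "Paralog conserved": ("Paralog conserved", "Paralog highly conserved"),
    "Paralog highly conserved": ("Paralog highly conserved",),
    "Synonymous": ("Synonymous",),
}

ALL_GENES_SET = "all_genes"
_BASES = np.array(["A", "C", "G", "T"])


def profile_rates(realised: Mapping[str, float]) -> dict[str, float]:
    """Convert realised per-class rates to disjoint profile rates."""
    missing = set(CLASS_NAMES) - set(realised)
    if missing:
        raise ConfigurationError(
            f"baseline_qv_rate: missing classes {sorted(missing)}"
        )
    r = dict(realised)
    prof = {
        "Benign missense": r["Benign missense"],
        "Damaging missense": r["Damaging missense"],
        "PTV": r["PTV"],
        "_inframe": r["All functional"] - r["PTV"] - r["Damaging missense"],
        "MPC 1": r["MPC 1"] - r["MPC 2"] - r["CCR 80"],
        "MPC 2": r["MPC 2"],
        "MTR ClinVar": r["MTR ClinVar"] - r["MTR De Novo"] - r["CCR 80"],
        "MTR De Novo": r["MTR De Novo"],
        "CCR 80": r["CCR 80"],
        "Paralog non-conserved": r["Paralog non-conserved"],
        "Paralog conserved": r["Paralog conserved"] - r["Paralog highly conserved"],
        "Paralog highly conserved": r["Paralog highly conserved"],
        "Synonymous": r["Synonymous"],
    }
    for name, v in prof.items():
        if v < -1e-12:
            raise ConfigurationError(
                "baseline_qv_rate: nested class rates inconsistent at "
                f"profile {name!r} (rate {v:.3g} < 0); e.g. the 'MPC 1' rate "
                "must cover the nested 'MPC 2' and 'CCR 80' rates"
            )
    return {k: max(0.0, v) for k, v in prof.items()}


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort (see module docstring)."""

    n_cases: Mapping[str, int] = field(default_factory=lambda: {"GGE": 2000})
    n_controls: int = 2000
    n_genes: int = 1000
    genes_per_set: Mapping[str, int] = field(
        default_factory=lambda: {"setA": 100, "setB": 100, "nonbrain_control": 100}
    )
    control_sets: tuple[str, ...] = ("nonbrain_control",)
    set_overlap: Mapping[tuple[str, str], float] = field(default_factory=dict)
    spiked_or: Mapping[tuple[str, str], float] = field(default_factory=dict)
    baseline_qv_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QV_RATES)
    )
    female_frac_cases: float = 0.536
    female_frac_controls: float = 0.194
    batch_labels: Mapping[str, float] = field(
        default_factory=lambda: {"ICE": 1100.0, "SureSelect": 2789.0}
    )
    pc_noise_sd: float = 1.0
    chrx_gene_frac: float = 0.05
    sex_effect_logit: float = 0.0
    filler_rate: float = 2.0
    af_fail_frac: float = 0.02
    shared_site_frac: float = 0.10
    second_site_frac: float = 0.10
    hom_frac: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not self.n_cases or any(v <= 0 for v in self.n_cases.values()):
            raise ConfigurationError("n_cases: each phenotype count must be > 0")
        for name in ("n_controls", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name}: must be > 0")
        for name in ("female_frac_cases", "female_frac_controls", "chrx_gene_frac",
                     "af_fail_frac", "shared_site_frac", "second_site_frac",
                     "hom_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: must be in [0, 1], got {v}")
        if self.pc_noise_sd < 0 or self.filler_rate < 0:
            raise ConfigurationError("pc_noise_sd and filler_rate must be >= 0")
        for sname, size in self.genes_per_set.items():
            if size <= 0:
                raise ConfigurationError(f"genes_per_set[{sname!r}]: must be > 0")
            if size > self.n_genes:
                raise ConfigurationError(
                    f"genes_per_set[{sname!r}]: {size} exceeds gene universe "
                    f"of {self.n_genes}"
                )
        for cs in self.control_sets:
            if cs not in self.genes_per_set:
                raise ConfigurationError(
                    f"control_sets: {cs!r} not declared in genes_per_set"
                )
        for (sname, cls), orr in self.spiked_or.items():
            if sname not in self.genes_per_set:
                raise ConfigurationError(
                    f"spiked_or: set {sname!r} not declared in genes_per_set"
                )
            if sname in self.control_sets:
                raise ConfigurationError(
                    f"spiked_or: control set {sname!r} must stay unspiked"
                )
            if cls not in CLASS_NAMES:
                raise ConfigurationError(f"spiked_or: unknown class {cls!r}")
            if orr < 0:
                raise ConfigurationError(
                    f"spiked_or[({sname!r}, {cls!r})]: odds ratio must be >= 0"
                )
        for (a, b), f in self.set_overlap.items():
            if a not in self.genes_per_set or b not in self.genes_per_set:
                raise ConfigurationError(
                    f"set_overlap: pair ({a!r}, {b!r}) references undeclared sets"
                )
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(
                    f"set_overlap[({a!r}, {b!r})]: fraction must be in [0, 1]"
                )
        if any(w <= 0 for w in self.batch_labels.values()):
            raise ConfigurationError("batch_labels: weights must be > 0")
        profile_rates(self.baseline_qv_rate)  # raises on inconsistency


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the ground truth of its spiked enrichments."""

    samples: pd.DataFrame
    variants: pd.DataFrame
    carriers: pd.DataFrame
    gene_sets: list[GeneSet]
    truth: pd.DataFrame
    config: SimConfig

    def write(self, outdir, vcf: bool = False) -> None:
        from . import io as ioh

        ioh.write_cohort(self, outdir, vcf=vcf)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_gene_sets(config: SimConfig) -> list[GeneSet]:
    """The declared sets plus an all-genes set and >= 1 unspiked control set.

    Deterministic given ``config.seed``; the same catalogue is produced inside
    :func:`generate_cohort`.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    genes = np.array(_gene_names(config.n_genes))
    members: dict[str, np.ndarray] = {}
    for name, size in config.genes_per_set.items():
        members[name] = np.sort(rng.choice(config.n_genes, size=size, replace=False))
    for (a, b), f in config.set_overlap.items():
        size_b = config.genes_per_set[b]
        k = int(round(f * size_b))
        if k > len(members[a]):
            raise ConfigurationError(
                f"set_overlap[({a!r}, {b!r})]: requested overlap {k} exceeds "
                f"size of {a!r}"
            )
        shared = rng.choice(members[a], size=k, replace=False)
        outside = np.setdiff1d(np.arange(config.n_genes), members[a])
        if size_b - k > len(outside):
            raise ConfigurationError(
                f"set_overlap[({a!r}, {b!r})]: not enough genes outside {a!r}"
            )
        rest = rng.choice(outside, size=size_b - k, replace=False)
        members[b] = np.sort(np.concatenate([shared, rest]))

    catalogue = []
    for name in config.genes_per_set:
        category = "control" if name in config.control_sets else "functional"
        catalogue.append(GeneSet(name, tuple(genes[members[name]]), category=category))
    if not any(gs.category == "control" for gs in catalogue):
        size = min(50, max(1, config.n_genes // 5))
        extra = np.sort(rng.choice(config.n_genes, size=size, replace=False))
        catalogue.append(
            GeneSet("control_nonexpressed", tuple(genes[extra]), category="control")
        )
    catalogue.append(GeneSet(ALL_GENES_SET, tuple(genes), category="all"))
    return catalogue


def _draw_scores(profile: str, n: int, rng: np.random.Generator) -> dict:
    """Annotation fields consistent with the intended profile, jittered."""
    nan = np.full(n, np.nan)
    none = np.full(n, np.nan, dtype=object)
    out = {
        "consequence": np.full(n, "missense", dtype=object),
        "pph2": none.copy(), "sift": none.copy(),
        "mpc": nan.copy(), "mtr": nan.copy(), "ccr": nan.copy(), "para_z": nan.copy(),
    }
    u = rng.uniform
    if profile == "Benign missense":
        out["pph2"] = np.full(n, "benign", dtype=object)
        out["sift"] = np.full(n, "tolerated", dtype=object)
        out["mpc"], out["mtr"], out["ccr"] = u(0, 0.9, n), u(0.85, 1.2, n), u(0, 70, n)
    elif profile == "Damaging missense":
        out["pph2"] = rng.choice(["possibly_damaging", "probably_damaging"], n)
        out["sift"] = np.full(n, "deleterious", dtype=object)
        out["mpc"], out["mtr"], out["ccr"] = u(0, 0.9, n), u(0.85, 1.2, n), u(0, 70, n)
    elif profile == "PTV":
        out["consequence"] = rng.choice(sorted(PTV_CONSEQUENCES), n)
    elif profile == "_inframe":
        out["consequence"] = np.full(n, "inframe_indel", dtype=object)
    elif profile == "MPC 1":
        out["mpc"], out["mtr"], out["ccr"] = u(1.0, 1.95, n), u(0.85, 1.2, n), u(0, 75, n)
    elif profile == "MPC 2":
        out["mpc"], out["mtr"], out["ccr"] = u(2.0, 3.5, n), u(0.85, 1.2, n), u(0, 75, n)
    elif profile == "MTR ClinVar":
        out["mpc"], out["mtr"], out["ccr"] = u(0, 0.9, n), u(0.57, 0.82, n), u(0, 75, n)
    elif profile == "MTR De Novo":
        out["mpc"], out["mtr"], out["ccr"] = u(0, 0.9, n), u(0.0, 0.56, n), u(0, 75, n)
    elif profile == "CCR 80":
        out["mpc"], out["mtr"], out["ccr"] = u(1.0, 1.95, n), u(0.57, 0.82, n), u(80, 100, n)
    elif profile == "Paralog non-conserved":
        out["para_z"] = u(-3.0, 0.0, n)
        out["mpc"], out["mtr"], out["ccr"] = u(0, 0.9, n), u(0.85, 1.2, n), u(0, 70, n)
    elif profile == "Paralog conserved":
        out["para_z"] = u(0.05, 0.95, n)
        out["mpc"], out["mtr"], out["ccr"] = u(0, 0.9, n), u(0.85, 1.2, n), u(0, 70, n)
    elif profile == "Paralog highly conserved":
        out["para_z"] = u(1.0, 4.0, n)
        out["mpc"], out["mtr"], out["ccr"] = u(0, 0.9, n), u(0.85, 1.2, n), u(0, 70, n)
    elif profile == "Synonymous":
        out["consequence"] = np.full(n, "synonymous", dtype=object)
    elif profile == "_filler":
        kind = rng.random(n)
        cons = np.full(n, "missense", dtype=object)
        cons[kind < 0.3] = "other"
        out["consequence"] = cons
        low = kind >= 0.7
        mpc = nan.copy(); mpc[low] = rng.uniform(0, 0.9, int(low.sum()))
        out["mpc"] = mpc
    else:  # pragma: no cover
        raise ValueError(f"unknown profile {profile!r}")
    return out


def _alleles(consequence: str, rng: np.random.Generator) -> tuple[str, str]:
    b = rng.choice(4, size=2, replace=False)
    ref, alt = _BASES[b[0]], _BASES[b[1]]
    if consequence in ("frameshift", "inframe_indel"):
        if rng.random() < 0.5:
            alt = ref + alt  # insertion
        else:
            ref, alt = ref + alt, ref  # deletion
    return str(ref), str(alt)


def _stratified_events(
    rng: np.random.Generator,
    sample_groups: list[tuple[np.ndarray, float]],
    gene_groups: list[tuple[np.ndarray, float]],
    p0: float,
    case_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli carrier draws over (sample, gene) strata with logit shifts."""
    si_all, gi_all = [], []
    base = logit(p0)
    for s_idx, s_off in sample_groups:
        for g_idx, g_delta in gene_groups:
            # gene-level enrichment applies to case samples only
            is_case_grp = bool(case_mask[s_idx[0]]) if len(s_idx) else False
            p = float(expit(base + s_off + (g_delta if is_case_grp else 0.0)))
            npairs = len(s_idx) * len(g_idx)
            if npairs == 0 or p <= 0.0:
                continue
            k = rng.binomial(npairs, p)
            if k == 0:
                continue
            flat = rng.choice(npairs, size=k, replace=False)
            si_all.append(s_idx[flat // len(g_idx)])
            gi_all.append(g_idx[flat % len(g_idx)])
    if not si_all:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.concatenate(si_all), np.concatenate(gi_all)


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (samples, variants, carriers, truth)."""
    config.validate()
    gene_sets = generate_gene_sets(config)
    rng_samples = _rng(config.seed, 1)
    rng_events = _rng(config.seed, 2)
    rng_sites = _rng(config.seed, 3)
    rng_filler = _rng(config.seed, 4)

    # ---- samples -------------------------------------------------------
    phenos, ids, sexes, batches = [], [], [], []
    for pheno, n in config.n_cases.items():
        ids += [f"{pheno.lower()}_{i:05d}" for i in range(n)]
        phenos += [pheno] * n
        sexes += list(np.where(rng_samples.random(n) < config.female_frac_cases, "F", "M"))
        batches += ["epi25"] * n
    n_ctrl = config.n_controls
    ids += [f"ctrl_{i:05d}" for i in range(n_ctrl)]
    phenos += ["control"] * n_ctrl
    sexes += list(np.where(rng_samples.random(n_ctrl) < config.female_frac_controls, "F", "M"))
    blabels = list(config.batch_labels)
    bw = np.array([config.batch_labels[b] for b in blabels], dtype=float)
    batches += list(rng_samples.choice(blabels, size=n_ctrl, p=bw / bw.sum()))
    n_samples = len(ids)
    samples = pd.DataFrame({"sample": ids, "phenotype": phenos, "sex": sexes,
                            "batch": batches})
    pcs = rng_samples.normal(0.0, config.pc_noise_sd, size=(n_samples, 10))
    for j in range(10):
        samples[f"PC{j+1}"] = pcs[:, j]

    # ---- gene universe -------------------------------------------------
    genes = np.array(_gene_names(config.n_genes))
    n_x = int(round(config.chrx_gene_frac * config.n_genes))
    x_idx = rng_samples.choice(config.n_genes, size=n_x, replace=False)
    chroms = rng_samples.choice([str(c) for c in range(1, 23)], size=config.n_genes)
    chroms = chroms.astype(object)
    chroms[x_idx] = "X"
    gene_start = 1_000_000 + 20_000 * np.arange(config.n_genes)

    set_members: dict[str, set[str]] = {gs.name: set(gs.genes) for gs in gene_sets}

    case_mask = np.array([p != "control" for p in phenos])
    case_idx = np.flatnonzero(case_mask)
    ctrl_idx = np.flatnonzero(~case_mask)
    female = np.array([s == "F" for s in sexes])

    prof_rates = profile_rates(config.baseline_qv_rate)

    # per-profile gene-level log-odds shifts from spiked (set, class) cells
    def gene_deltas(profile: str) -> np.ndarray:
        delta = np.zeros(config.n_genes)
        for (sname, cls), orr in config.spiked_or.items():
            if profile in CLASS_TO_PROFILES[cls] and orr > 0:
                in_set = np.isin(genes, list(set_members[sname]))
                delta[in_set] += math.log(orr)
        return delta

    # ---- carrier events ------------------------------------------------
    site_rows: list[tuple] = []     # (gene_idx, profile, carriers[(sample, ac)])
    ev_profile: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for profile in PROFILES:
        p0 = prof_rates[profile] / 1000.0
        if p0 <= 0:
            continue
        delta = gene_deltas(profile)
        vals = np.unique(delta)
        gene_groups = [(np.flatnonzero(delta == v), float(v)) for v in vals]
        if config.sex_effect_logit != 0.0:
            sgroups = [
                (np.intersect1d(case_idx, np.flatnonzero(female)), config.sex_effect_logit),
                (np.intersect1d(case_idx, np.flatnonzero(~female)), 0.0),
                (np.intersect1d(ctrl_idx, np.flatnonzero(female)), config.sex_effect_logit),
                (np.intersect1d(ctrl_idx, np.flatnonzero(~female)), 0.0),
            ]
        else:
            sgroups = [(case_idx, 0.0), (ctrl_idx, 0.0)]
        si, gi = _stratified_events(rng_events, sgroups, gene_groups, p0, case_mask)
        ev_profile[profile] = (si, gi)

    # ---- turn events into sites ---------------------------------------
    for profile in PROFILES:
        if profile not in ev_profile:
            continue
        si, gi = ev_profile[profile]
        n_ev = len(si)
        if n_ev == 0:
            continue
        communal = rng_sites.random(n_ev) < config.shared_site_frac
        # communal events pair up within a gene into shared (MAC 2-3) sites
        by_gene: dict[int, list[int]] = {}
        for e in np.flatnonzero(communal):
            by_gene.setdefault(int(gi[e]), []).append(e)
        handled = np.zeros(n_ev, dtype=bool)
        for g, evs in sorted(by_gene.items()):
            i = 0
            while i + 1 < len(evs):
                size = 3 if (len(evs) - i >= 3 and rng_sites.random() < 0.3) else 2
                group = evs[i:i + size]
                i += size
                site_rows.append((g, profile, [(int(si[e]), 1) for e in group]))
                for e in group:
                    handled[e] = True
        for e in np.flatnonzero(~handled):
            ac = 2 if rng_sites.random() < config.hom_frac else 1
            site_rows.append((int(gi[e]), profile, [(int(si[e]), ac)]))
        # occasional second site in the same carrier gene (multi-QV collapsing)
        extra = np.flatnonzero(rng_sites.random(n_ev) < config.second_site_frac)
        for e in extra:
            site_rows.append((int(gi[e]), profile, [(int(si[e]), 1)]))

    # ---- filler variants (no class; exercises filters and covariates) --
    n_filler = rng_filler.poisson(n_samples * config.n_genes / 1000.0 * config.filler_rate)
    if n_filler:
        fs = rng_filler.integers(0, n_samples, size=n_filler)
        fg = rng_filler.integers(0, config.n_genes, size=n_filler)
        n_hm = int(0.05 * n_filler)  # grouped into MAC > 3 sites, later filtered
        i = 0
        while i + 4 <= n_hm:
            g = int(fg[i])
            grp_samples = np.unique(fs[i:i + 5])
            site_rows.append((g, "_filler", [(int(s), 1) for s in grp_samples]))
            i += 5
        for e in range(n_hm, n_filler):
            site_rows.append((int(fg[e]), "_filler", [(int(fs[e]), 1)]))

    # ---- materialise variant and carrier tables ------------------------
    site_counter: dict[int, int] = {}
    v_rows, c_rows = [], []
    # draw per-profile score blocks in one go for speed
    order = sorted(range(len(site_rows)), key=lambda k: (site_rows[k][1], k))
    prof_of = [site_rows[k][1] for k in order]
    blocks: dict[str, dict] = {}
    starts: dict[str, int] = {}
    for profile in sorted(set(prof_of)):
        n = prof_of.count(profile)
        blocks[profile] = _draw_scores(profile, n, rng_sites)
        starts[profile] = 0
    for k in order:
        g, profile, carr = site_rows[k]
        blk, j = blocks[profile], starts[profile]
        starts[profile] += 1
        cons = str(blk["consequence"][j])
        off = site_counter.get(g, 0)
        site_counter[g] = off + 1
        pos = int(gene_start[g] + off)
        ref, alt = _alleles(cons, rng_sites)
        gaf, daf = 0.0, 0.0
        rr = rng_sites.random()
        if rr < config.af_fail_frac:
            if rng_sites.random() < 0.5:
                gaf = 1e-3          # too common in gnomAD
            else:
                daf = 1e-4          # present in DiscovEHR
        elif rr < config.af_fail_frac + 0.10:
            gaf = 1e-5              # seen in gnomAD but below threshold
        mac_total = sum(ac for _, ac in carr)
        if mac_total > 3 and profile != "_filler":  # pragma: no cover
            raise AssertionError("class sites must stay ultra-rare")
        v_rows.append((
            str(chroms[g]), pos, ref, alt, str(genes[g]), cons,
            blk["pph2"][j], blk["sift"][j],
            blk["mpc"][j], blk["mtr"][j], blk["ccr"][j], blk["para_z"][j],
            gaf, daf,
        ))
        for s, ac in carr:
            c_rows.append((str(chroms[g]), pos, ref, alt, ids[s], ac))

    variants = pd.DataFrame(v_rows, columns=VARIANT_COLUMNS)
    variants = variants.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
    variants = variants.reset_index(drop=True)
    carriers = pd.DataFrame(
        c_rows, columns=["chrom", "pos", "ref", "alt", "sample", "allele_count"]
    )
    carriers = carriers.sort_values(
        ["chrom", "pos", "ref", "alt", "sample"], kind="mergesort"
    ).reset_index(drop=True)

    # ---- truth ---------------------------------------------------------
    t_rows = []
    for gs in gene_sets:
        for cls in CLASS_NAMES:
            lo = math.log(config.spiked_or[(gs.name, cls)]) \
                if (gs.name, cls) in config.spiked_or else 0.0
            for pheno in config.n_cases:
                t_rows.append((gs.name, cls, pheno, lo))
    truth = pd.DataFrame(t_rows, columns=["gene_set", "class", "phenotype", "log_odds"])

    logger.info(
        "simulated cohort: %d samples, %d variants, %d carrier records",
        n_samples, len(variants), len(carriers),
    )
    return SyntheticCohort(samples, variants, carriers, gene_sets, truth, config)
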