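"""Readers/writers for every format the pipeline touches, plus the pipeline.

All tabular files are tab-separated UTF-8 with a header row; the missing-value
marker is the empty string (never ``.``).  Gene sets use the standard GMT
layout (``name<TAB>description<TAB>gene...``, one set per line); the
description slot carries a ``category:<name>`` token so catalogue categories
survive a round trip.  A minimal VCF 4.2 emitter/reader is provided for
cohorts exchanged as multi-sample VCF with annotation scores in INFO.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .collapse import GeneSet
from .errors import ConfigurationError, ParseError
from .qv import CARRIER_COLUMNS, VARIANT_COLUMNS, UrvFilterConfig, default_class_rules

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["sample", "phenotype", "sex", "batch"] + [f"PC{i}" for i in range(1, 11)]

_VARIANT_FLOATS = ["mpc", "mtr", "ccr", "para_z", "gnomad_af", "discovehr_af"]

#: INFO key -> variant column mapping used by the VCF reader/writer
DEFAULT_INFO_KEYS = {
    "GENE": "gene", "CSQ": "consequence", "PPH2": "pph2", "SIFT": "sift",
    "MPC": "mpc", "MTR": "mtr", "CCR": "ccr", "PARAZ": "para_z",
    "GNOMAD_AF": "gnomad_af", "DISCOVEHR_AF": "discovehr_af",
}


# --------------------------------------------------------------------------
# TSV schemas
# --------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def write_samples_tsv(samples: pd.DataFrame, path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: samples table missing columns {sorted(missing)}")
    for c in ("sample", "phenotype", "sex", "batch"):
        df[c] = df[c].astype(str)
    for i in range(1, 11):
        df[f"PC{i}"] = df[f"PC{i}"].astype(float)
    return df[SAMPLE_COLUMNS]


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    variants[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: variants table missing columns {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    for c in ("ref", "alt", "gene", "consequence"):
        df[c] = df[c].astype(str)
    for c in _VARIANT_FLOATS:
        df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)
    return df[VARIANT_COLUMNS]


def write_carriers_tsv(carriers: pd.DataFrame, path) -> None:
    carriers[CARRIER_COLUMNS].to_csv(path, sep="\t", index=False)


def read_carriers_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(CARRIER_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: carriers table missing columns {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    for c in ("ref", "alt", "sample"):
        df[c] = df[c].astype(str)
    df["allele_count"] = df["allele_count"].astype(int)
    return df[CARRIER_COLUMNS]


def write_results_tsv(results: pd.DataFrame, path) -> None:
    """Results grid at 6 significant digits (small p values print scientific)."""
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_tsv(path) -> pd.DataFrame:
    return _read_tsv(path)


# --------------------------------------------------------------------------
# GMT
# --------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT catalogue; duplicate set names are an error, duplicate
    genes within a set are deduplicated with a warning."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            if len(set(genes)) != len(genes):
                logger.warning(
                    "%s:%d: duplicate genes in set %s deduplicated", path, lineno, name
                )
            category = desc.split(":", 1)[1] if desc.startswith("category:") else "functional"
            sets.append(GeneSet(name, tuple(genes), category=category, description=desc))
    return sets


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, f"category:{gs.category}", *gs.genes]) + "\n")


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

def write_vcf(variants: pd.DataFrame, carriers: pd.DataFrame,
              sample_ids: list[str], path) -> None:
    """Emit a minimal multi-sample VCF 4.2 with scores as INFO key-values."""
    inv_keys = {v: k for k, v in DEFAULT_INFO_KEYS.items()}
    from .qv import variant_key_frame

    ckeys = variant_key_frame(carriers)
    carr_map: dict[str, dict[str, int]] = {}
    for key, s, ac in zip(ckeys, carriers["sample"], carriers["allele_count"]):
        carr_map.setdefault(key, {})[s] = int(ac)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for key, col in DEFAULT_INFO_KEYS.items():
            typ = "String" if col in ("gene", "consequence", "pph2", "sift") else "Float"
            fh.write(
                f'##INFO=<ID={key},Number=1,Type={typ},Description="{col}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                 + "FORMAT\t" + "\t".join(sample_ids) + "\n")
        vkeys = variant_key_frame(variants)
        for (_, v), key in zip(variants.iterrows(), vkeys):
            info = []
            for col in DEFAULT_INFO_KEYS.values():
                val = v[col]
                if isinstance(val, float) and np.isnan(val):
                    continue
                if pd.isna(val):
                    continue
                if isinstance(val, float):
                    info.append(f"{inv_keys[col]}={val:.6g}")
                else:
                    info.append(f"{inv_keys[col]}={val}")
            row = [str(v["chrom"]), str(int(v["pos"])), ".", str(v["ref"]),
                   str(v["alt"]), ".", "PASS", ";".join(info) or ".", "GT"]
            cm = carr_map.get(key, {})
            for s in sample_ids:
                ac = cm.get(s, 0)
                row.append({0: "0/0", 1: "0/1", 2: "1/1"}[ac])
            fh.write("\t".join(row) + "\n")


def read_vcf_cohort(path, info_key_map: dict | None = None):
    """Read a multi-sample VCF into (variants, carriers) tables.

    Multiallelic records are split into one row per ALT allele; positions are
    taken as-is.  A missing mapped INFO key becomes a missing score, counted
    in one summary warning.
    """
    from cyvcf2 import VCF

    info_key_map = dict(DEFAULT_INFO_KEYS if info_key_map is None else info_key_map)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    v_rows, c_rows = [], []
    n_missing_info = 0
    for rec in vcf:
        gts = rec.genotypes  # [allele_a, allele_b, phased]
        for alt_i, alt in enumerate(rec.ALT, start=1):
            row = {"chrom": str(rec.CHROM), "pos": int(rec.POS),
                   "ref": str(rec.REF), "alt": str(alt)}
            for key, col in info_key_map.items():
                val = rec.INFO.get(key)
                if val is None:
                    n_missing_info += 1
                    row[col] = np.nan if col in _VARIANT_FLOATS else np.nan
                else:
                    row[col] = float(val) if col in _VARIANT_FLOATS else str(val)
            for col in ("gnomad_af", "discovehr_af"):
                if pd.isna(row.get(col, np.nan)):
                    row[col] = 0.0
            v_rows.append(row)
            for s_i, g in enumerate(gts):
                ac = sum(1 for a in g[:-1] if a == alt_i)
                if ac > 0:
                    c_rows.append({
                        "chrom": str(rec.CHROM), "pos": int(rec.POS),
                        "ref": str(rec.REF), "alt": str(alt),
                        "sample": sample_ids[s_i], "allele_count": min(ac, 2),
                    })
    if n_missing_info:
        logger.warning("%d missing INFO values treated as missing scores",
                       n_missing_info)
    variants = pd.DataFrame(v_rows, columns=VARIANT_COLUMNS)
    for c in _VARIANT_FLOATS:
        variants[c] = pd.to_numeric(variants[c], errors="coerce").astype(float)
    carriers = pd.DataFrame(c_rows, columns=CARRIER_COLUMNS)
    return variants, carriers


# --------------------------------------------------------------------------
# cohort directory
# --------------------------------------------------------------------------

def write_cohort(cohort, outdir, vcf: bool = False) -> Path:
    """Write a synthetic cohort (samples/variants/carriers/GMT/truth) to a dir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_samples_tsv(cohort.samples, out / "samples.tsv")
    write_variants_tsv(cohort.variants, out / "variants.tsv")
    write_carriers_tsv(cohort.carriers, out / "carriers.tsv")
    write_gmt(cohort.gene_sets, out / "gene_sets.gmt")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    if vcf:
        write_vcf(cohort.variants, cohort.carriers,
                  list(cohort.samples["sample"]), out / "cohort.vcf")
    return out


def read_cohort(indir):
    """Read a cohort directory back into (samples, variants, carriers, gene_sets)."""
    d = Path(indir)
    return (
        read_samples_tsv(d / "samples.tsv"),
        read_variants_tsv(d / "variants.tsv"),
        read_carriers_tsv(d / "carriers.tsv"),
        read_gmt(d / "gene_sets.gmt"),
    )


# --------------------------------------------------------------------------
# run configuration and end-to-end pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run configuration (paths, thresholds, grid dimensions)."""

    samples: str
    gene_sets: str
    variants: str | None = None
    carriers: str | None = None
    vcf: str | None = None
    phenotypes: list[str] | None = None
    mac_max: int = 3
    gnomad_af_max: float = 2e-5
    discovehr_af_max: float = 0.0
    damaging_requires_both: bool = True
    alpha: float = 0.05
    n_pcs: int = 10
    out_dir: str = "ursaburden_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config fields: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.vcf is None and (self.variants is None or self.carriers is None):
            raise ConfigurationError(
                "either 'vcf' or both 'variants' and 'carriers' paths are required"
            )
        paths = {"samples": self.samples, "gene_sets": self.gene_sets,
                 "variants": self.variants, "carriers": self.carriers,
                 "vcf": self.vcf}
        for name, p in paths.items():
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name}: file not found: {p}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha: must be in (0, 1), got {self.alpha}")
        if not 0 <= self.n_pcs <= 10:
            raise ConfigurationError(f"n_pcs: must be in [0, 10], got {self.n_pcs}")
        UrvFilterConfig(self.mac_max, self.gnomad_af_max, self.discovehr_af_max)

    def urv_filter(self) -> UrvFilterConfig:
        return UrvFilterConfig(self.mac_max, self.gnomad_af_max, self.discovehr_af_max)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full burden grid from files and write all report artifacts.

    Outputs under ``config.out_dir``: ``results.tsv`` (full grid including the
    synonymous control track), ``forest.tsv``, ``manifest.json`` (config echo,
    seed, per-stage filter-funnel counts) and ``run.log``.  Reruns of an
    identical configuration produce byte-identical tables.
    """
    from .stats import run_grid

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ursaburden")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        samples = read_samples_tsv(config.samples)
        if config.vcf is not None:
            variants, carriers = read_vcf_cohort(config.vcf)
        else:
            variants = read_variants_tsv(config.variants)
            carriers = read_carriers_tsv(config.carriers)
        gene_sets = read_gmt(config.gene_sets)
        rules = default_class_rules(config.damaging_requires_both)
        grid = run_grid(
            samples, variants, carriers, gene_sets,
            phenotypes=config.phenotypes, rules=rules,
            urv_cfg=config.urv_filter(), alpha=config.alpha, n_pcs=config.n_pcs,
        )
        grid.to_tsv(out / "results.tsv")
        grid.forest_frame().to_csv(out / "forest.tsv", sep="\t", index=False,
                                   float_format="%.6g")
        manifest = {
            "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
            "grid": grid.meta,
            "n_adjusted_tests": grid.n_adjusted_tests,
            "n_synonymous_tests": grid.n_synonymous_tests,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
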