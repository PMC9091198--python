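"""Readers and writers for every on-disk format the pipelines touch.

Formats
-------
* Genotype panel TSV: one row per sample, first column ``sample_id``,
  one column per SNP with header ``rsid`` or ``rsid:EA:OA`` (effect and
  other allele), optional VNTR-dosage column (default name ``VNTR``).
* VCF (via cyvcf2): dosage is the ALT-allele count; multi-allelic records
  among the tag SNPs are rejected; samples with any missing genotype are
  dropped (listwise deletion) with a logged count.
* Summary-statistics TSV: whitespace/tab delimited with a configurable
  column map (defaults SNP/A1/A2/BETA/SE/Z/N/P); gzip transparent.
* Prediction model JSON, LD matrix TSV (+ JSON sidecar), association
  result TSV/JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .ld import LDMatrix
from .panel import TagPanel
from .prediction import PredictionModel
from .summary_assoc import SummaryStats, VNTRAssocResult

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "read_model",
    "write_model",
    "read_ld",
    "write_ld",
    "write_result",
    "read_phenotypes",
    "write_phenotypes",
]

logger = logging.getLogger(__name__)

DEFAULT_COLUMN_MAP = {
    "snp": "SNP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "se": "SE",
    "z": "Z",
    "n": "N",
    "p": "P",
}


def read_summary_stats(path, column_map: dict | None = None) -> SummaryStats:
    """Parse a delimited summary-statistics file.

    Mandatory columns: SNP id, both alleles, N, and at least one of
    (BETA and SE) or Z.  Rows with unparseable numerics in the required
    fields are dropped with a logged count.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=None, engine="python", compression="infer")
    cols = set(df.columns)
    missing = [cmap[k] for k in ("snp", "effect_allele", "other_allele", "n")
               if cmap[k] not in cols]
    has_beta = cmap["beta"] in cols and cmap["se"] in cols
    has_z = cmap["z"] in cols
    if not (has_beta or has_z):
        missing.append(f"{cmap['beta']}+{cmap['se']} or {cmap['z']}")
    if missing:
        raise SchemaError(
            f"summary-stats file {path} lacks column(s) {missing}; "
            f"found {sorted(cols)}"
        )
    numeric = [cmap["n"]]
    if has_beta:
        numeric += [cmap["beta"], cmap["se"]]
    if has_z:
        numeric.append(cmap["z"])
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    before = len(df)
    df = df.dropna(subset=numeric)
    if len(df) < before:
        logger.warning("dropped %d row(s) with unparseable numerics", before - len(df))
    if df.empty:
        raise SchemaError(f"no usable rows in {path}")
    get = lambda k: df[cmap[k]].to_numpy() if cmap[k] in cols else None
    p = None
    if cmap["p"] in cols:
        p = pd.to_numeric(df[cmap["p"]], errors="coerce").to_numpy()
        if np.isnan(p).any():
            p = None
    return SummaryStats(
        snp_ids=df[cmap["snp"]].astype(str).tolist(),
        effect_alleles=df[cmap["effect_allele"]].astype(str).tolist(),
        other_alleles=df[cmap["other_allele"]].astype(str).tolist(),
        n=get("n"),
        beta=get("beta") if has_beta else None,
        se=get("se") if has_beta else None,
        z=get("z") if has_z else None,
        p=p,
    )


def write_summary_stats(stats: SummaryStats, path) -> None:
    df = pd.DataFrame({"SNP": stats.snp_ids, "A1": stats.effect_alleles,
                       "A2": stats.other_alleles})
    if stats.beta is not None:
        df["BETA"] = stats.beta
        df["SE"] = stats.se
    df["Z"] = stats.z
    df["N"] = stats.n
    if stats.p is not None:
        df["P"] = stats.p
    df.to_csv(path, sep="\t", index=False)


# -- genotype panels ----------------------------------------------------------


def write_genotypes_tsv(panel: TagPanel, path, vntr_column: str = "VNTR") -> None:
    headers = []
    for j, s in enumerate(panel.snp_ids):
        ea = panel.effect_alleles[j]
        oa = panel.other_alleles[j] if panel.other_alleles else None
        headers.append(f"{s}:{ea}:{oa}" if oa else f"{s}:{ea}")
    df = pd.DataFrame(panel.genotypes, columns=headers)
    df.insert(0, "sample_id", panel.sample_ids)
    if panel.vntr_dosage is not None:
        df[vntr_column] = panel.vntr_dosage
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_genotypes_tsv(path, vntr_column: str = "VNTR") -> TagPanel:
    df = pd.read_csv(path, sep="\t", compression="infer")
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: first column must be 'sample_id'")
    sample_ids = df["sample_id"].astype(str).tolist()
    snp_cols = [c for c in df.columns if c not in ("sample_id", vntr_column)]
    if not snp_cols:
        raise SchemaError(f"{path}: no SNP columns found")
    snp_ids, eff, oth = [], [], []
    any_other = False
    for c in snp_cols:
        parts = c.split(":")
        snp_ids.append(parts[0])
        eff.append(parts[1] if len(parts) > 1 else "A")
        if len(parts) > 2:
            oth.append(parts[2])
            any_other = True
        else:
            oth.append("N")
    geno = df[snp_cols].to_numpy(dtype=float)
    if np.isnan(geno).any():
        bad = np.isnan(geno).any(axis=1)
        logger.warning("dropping %d sample(s) with missing genotypes", int(bad.sum()))
        keep = ~bad
        geno = geno[keep]
        sample_ids = [s for s, k in zip(sample_ids, keep) if k]
        df = df.loc[keep]
    vntr = None
    if vntr_column in df.columns:
        vntr = df[vntr_column].to_numpy(dtype=float)
    return TagPanel(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        effect_alleles=eff,
        other_alleles=oth if any_other else None,
        genotypes=geno,
        vntr_dosage=vntr,
        source=str(path),
    )


def read_genotypes_vcf(path, snp_ids: list | None = None) -> TagPanel:
    """Read tag-SNP dosages from a VCF; dosage counts the ALT allele.

    ``snp_ids`` optionally restricts to (and orders by) the given ids.
    Samples with any missing genotype among the kept records are removed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, eff, oth, rows = [], [], [], []
    wanted = set(snp_ids) if snp_ids else None
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if wanted is not None and vid not in wanted:
            continue
        if len(variant.ALT) != 1:
            raise SchemaError(
                f"multi-allelic record {vid} in {path}; tag SNPs must be biallelic"
            )
        gts = variant.genotypes  # [allele1, allele2, phased]
        dosage = np.empty(len(samples))
        for i, gt in enumerate(gts):
            a = [x for x in gt[:2]]
            if -1 in a:
                dosage[i] = np.nan
            else:
                dosage[i] = float(sum(1 for x in a if x != 0))
        ids.append(vid)
        eff.append(variant.ALT[0])
        oth.append(variant.REF)
        rows.append(dosage)
    if not rows:
        raise SchemaError(f"no usable records in {path}")
    geno = np.column_stack(rows)
    bad = np.isnan(geno).any(axis=1)
    if bad.any():
        logger.warning(
            "dropping %d sample(s) with missing genotypes (listwise)", int(bad.sum())
        )
        geno = geno[~bad]
        samples = [s for s, b in zip(samples, bad) if not b]
    panel = TagPanel(
        sample_ids=samples,
        snp_ids=ids,
        effect_alleles=eff,
        other_alleles=oth,
        genotypes=geno,
        source=str(path),
    )
    if snp_ids:
        missing = [s for s in snp_ids if s not in ids]
        if missing:
            raise SchemaError(f"VCF {path} lacks requested SNPs: {missing}")
        panel = panel.subset_snps(snp_ids)
    return panel


# -- model / LD / results -----------------------------------------------------


def write_model(model: PredictionModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def read_model(path) -> PredictionModel:
    return PredictionModel.from_dict(json.loads(Path(path).read_text()))


def write_ld(ld: LDMatrix, path) -> None:
    """LD as TSV with SNP-id header row/column; JSON sidecar for provenance."""
    df = pd.DataFrame(ld.values, index=ld.snp_ids, columns=ld.snp_ids)
    df.to_csv(path, sep="\t", float_format="%.12g")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "n_panel": ld.n_panel,
                "source": ld.source,
                "epsilon": ld.epsilon,
                "effect_alleles": ld.effect_alleles,
                "other_alleles": ld.other_alleles,
            },
            indent=2,
        )
        + "\n"
    )


def read_ld(path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{path}: row and column SNP ids differ")
    meta = {"n_panel": 0, "source": str(path), "epsilon": 0.0}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return LDMatrix(
        snp_ids=[str(s) for s in df.index],
        values=df.to_numpy(dtype=float),
        n_panel=int(meta["n_panel"]),
        source=str(meta["source"]),
        epsilon=float(meta["epsilon"]),
        effect_alleles=meta.get("effect_alleles"),
        other_alleles=meta.get("other_alleles"),
    )


def write_result(result: VNTRAssocResult, path, label: str = "phenotype") -> None:
    """One-row TSV plus a JSON file with full provenance."""
    row = {
        "phenotype": label,
        "method": result.method,
        "alpha_hat": result.alpha_hat,
        "se": result.se_alpha,
        "z": result.z_alpha,
        "p": result.p_value,
        "k_wv": result.k_wv,
        "n": result.n_used,
        "snps_used": ",".join(result.snps_used),
        "flags": ";".join(f"{k}={v}" for k, v in sorted(result.mode_flags.items())),
    }
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)
    Path(str(path) + ".json").write_text(
        json.dumps({"label": label, **result.to_dict()}, indent=2, default=str) + "\n"
    )


# -- phenotypes ---------------------------------------------------------------


def write_phenotypes(pheno, path) -> None:
    from .individual import PhenotypeData  # noqa: F401  (type only)

    df = pd.DataFrame({"sample_id": pheno.sample_ids, "y": pheno.y})
    if pheno.covariates is not None:
        names = pheno.covariate_names or [
            f"cov{i + 1}" for i in range(pheno.covariates.shape[1])
        ]
        for i, name in enumerate(names):
            df[name] = pheno.covariates[:, i]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path, y_column: str = "y"):
    from .individual import PhenotypeData

    df = pd.read_csv(path, sep="\t", compression="infer")
    if "sample_id" not in df.columns or y_column not in df.columns:
        raise SchemaError(f"{path}: need 'sample_id' and '{y_column}' columns")
    cov_cols = [c for c in df.columns if c not in ("sample_id", y_column)]
    df = df.dropna()
    return PhenotypeData(
        sample_ids=df["sample_id"].astype(str).tolist(),
        y=df[y_column].to_numpy(dtype=float),
        covariates=df[cov_cols].to_numpy(dtype=float) if cov_cols else None,
        covariate_names=cov_cols or None,
    )
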