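"""Readers and writers for the on-disk TSV/YAML formats.

TSV is the interchange format throughout (auditable plain text): z-value
tracks in, decision tables and model parameters out.  A thin VCF adapter
extracts diploid GT dosages for genotype input.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig
from .fdr import DecisionResult
from .hmm_core import EmissionMixture, RegionHMM, ZSeries
from .model_select import ChromosomeModel
from .ztransform import GenotypeMatrix, p_to_z


class InputError(ValueError):
    """Malformed on-disk input."""


def read_ztrack(path, chrom: str | None = None, p_floor: float = 1e-15) -> ZSeries:
    """Read a per-SNP track TSV with columns ``snp_id`` and ``z`` or ``p``.

    A file carrying only p-values is coerced to z-values on load via the
    upper-tail transform.  Malformed rows are reported with their line
    numbers; duplicate snp_ids are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = set(df.columns)
    if "snp_id" not in cols or not ({"z", "p"} & cols):
        raise InputError(
            f"{path}: expected columns 'snp_id' and 'z' (or 'p'); got {sorted(cols)}"
        )
    dup = df["snp_id"].duplicated()
    if dup.any():
        raise InputError(
            f"{path}: duplicate snp_id at line(s) {(df.index[dup] + 2).tolist()[:5]}"
        )
    col = "z" if "z" in cols else "p"
    bad = pd.to_numeric(df[col], errors="coerce").isna()
    if bad.any():
        raise InputError(
            f"{path}: non-numeric {col} at line(s) {(df.index[bad] + 2).tolist()[:5]}"
        )
    # exact strtod parse (pd.to_numeric trades precision for speed)
    z = df[col].astype(float).to_numpy()
    if col == "p":
        z = p_to_z(z, p_floor=p_floor)
    return ZSeries(
        chrom=chrom or path.stem, z=z, snp_ids=df["snp_id"].tolist()
    )


def _provenance_header(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_ztrack(path, z: ZSeries, provenance: dict | None = None) -> None:
    ids = z.snp_ids or [f"{z.chrom}_snp{i + 1}" for i in range(len(z))]
    df = pd.DataFrame({"snp_id": ids, "z": z.z})
    if z.theta_truth is not None:
        df["theta"] = z.theta_truth
    buf = _io.StringIO()
    buf.write(_provenance_header(provenance))
    df.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def write_results(path, result: DecisionResult, provenance: dict | None = None) -> None:
    """Write the decision table with a '#'-prefixed provenance header."""
    buf = _io.StringIO()
    header = {"alpha": result.alpha, "l_cut": result.l_cut}
    header.update(provenance or {})
    for k, v in header.items():
        buf.write(f"# {k}: {v}\n")
    result.records.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def read_results(path) -> DecisionResult:
    path = Path(path)
    alpha, l_cut = None, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(":")
            if key.strip() == "alpha":
                alpha = float(val)
            elif key.strip() == "l_cut":
                l_cut = int(val)
    df = pd.read_csv(path, sep="\t", comment="#")
    if alpha is None or l_cut is None:
        raise InputError(f"{path}: missing alpha/l_cut provenance header")
    return DecisionResult(alpha=alpha, l_cut=l_cut, records=df)


def read_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError(f"{path}: config must be a key-value mapping")
    try:
        return AnalysisConfig.from_dict(data)
    except (TypeError, ValueError) as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_config(path, config: AnalysisConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def model_to_dict(model: ChromosomeModel) -> dict:
    return {
        "chrom": model.chrom,
        "m": int(model.m),
        "changepoints": [int(x) for x in model.w],
        "lambda": float(model.lambda_used),
        "total_loglik": float(model.total_loglik),
        "regions": [
            {
                "a01": float(r.a01),
                "a10": float(r.a10),
                "xi": [float(x) for x in r.f1.xi],
                "mu": [float(x) for x in r.f1.mu],
                "sigma": [float(x) for x in r.f1.sigma],
            }
            for r in model.regions
        ],
    }


def write_model(path, model: ChromosomeModel, provenance: dict | None = None) -> None:
    """Serialize the fitted per-region parameters (one region per record)."""
    Path(path).write_text(
        _provenance_header(provenance)
        + yaml.safe_dump(model_to_dict(model), sort_keys=False)
    )


def read_model(path) -> ChromosomeModel:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    regions = [
        RegionHMM.from_rates(
            r["a01"], r["a10"],
            EmissionMixture(np.array(r["xi"]), np.array(r["mu"]), np.array(r["sigma"])),
        )
        for r in d["regions"]
    ]
    return ChromosomeModel(
        chrom=d["chrom"], w=np.array(d["changepoints"], dtype=int), m=d["m"],
        regions=regions, total_loglik=d["total_loglik"], lambda_used=d["lambda"],
    )


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Genotype TSV: header of SNP ids plus a ``status`` column; one row
    per subject; codes 0/1/2 with empty or NA cells treated as missing."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "status" not in df.columns:
        raise InputError(f"{path}: genotype table needs a 'status' column")
    status = df.pop("status").to_numpy()
    return GenotypeMatrix(
        codes=df.to_numpy(dtype=float), status=status, snp_ids=list(df.columns)
    )


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Thin VCF adapter: diploid unphased GT to dosage of the ALT allele.

    Sample columns become subjects; half-calls and './.' are missing.
    Disease status is not part of VCF and must be attached afterwards, so
    this returns codes and snp_ids with an all-control placeholder status
    replaced by the caller.
    """
    rows, ids, samples = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            if samples is None:
                raise InputError(f"{path}: missing #CHROM header line")
            ids.append(parts[2] if parts[2] != "." else f"{parts[0]}:{parts[1]}")
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            dos = []
            for s in parts[9:]:
                gt = s.split(":")[gt_i].replace("|", "/")
                alleles = gt.split("/")
                if len(alleles) != 2 or "." in alleles:
                    dos.append(np.nan)
                else:
                    dos.append(float(int(alleles[0]) + int(alleles[1])))
            rows.append(dos)
    codes = np.asarray(rows, dtype=float).T  # subjects x snps
    status = np.zeros(codes.shape[0], dtype=int)
    status[: max(1, len(status) // 2)] = 1  # placeholder; caller must set
    return GenotypeMatrix(codes=codes, status=status, snp_ids=ids)
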