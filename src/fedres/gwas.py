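"""Federated genome-wide association.

Genotypes live per node as a sample-by-variant matrix of alternate-allele
dosages (0/1/2, additive coding) built from VCF, alongside a phenotype table
sharing sample ids. Association runs per SNP as a GLM with the dosage column
appended to the covariate design, in one of two modes:

* ``federated`` — one distributed IRLS fit per variant, exactly equal to the
  pooled analysis but requiring one network round per IRLS iteration per
  variant;
* ``meta``      — each node runs an independent local scan and returns only
  (beta, se, n) per variant; the client combines them by inverse-variance
  fixed-effect meta-analysis in a single round.

Variant lists must be identical across nodes: harmonisation (imputation,
strand flipping) is assumed done upstream and is not attempted here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy.stats import norm

from .federation import ClientSession, GuardContext, server_op
from .glm import (
    FederatedBlockedError,
    GLMError,
    GLMSpec,
    design_matrix,
    fit_irls,
    glm_server_contribution,
    _federated_irls,
    _raise_on_block,
)


class GwasError(Exception):
    pass


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    id: str


@dataclass
class GenotypeStudy:
    """Dosage matrix plus variant metadata; the desk-scale stand-in for a
    binary genotype container. ``dosages`` is samples x variants, float,
    with NaN for missing calls."""

    samples: list[str]
    variants: list[Variant]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise GwasError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency over called genotypes."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        freq = np.nan_to_num(freq, nan=0.0)
        return np.minimum(freq, 1.0 - freq)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_variants(self, keep: Sequence[int] | np.ndarray) -> "GenotypeStudy":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeStudy(
            samples=list(self.samples),
            variants=[self.variants[i] for i in keep],
            dosages=self.dosages[:, keep],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: sample id plus one dosage column per variant."""
        out = pd.DataFrame({"sample_id": self.samples})
        for j, variant in enumerate(self.variants):
            out[variant.id] = self.dosages[:, j]
        return out


# ---------------------------------------------------------------------------
# VCF I/O

def read_vcf_genotypes(path: str | Path) -> GenotypeStudy:
    """Read a VCF 4.x (plain or gzip) into a :class:`GenotypeStudy`.

    Dosage is the count of alternate alleles in GT; missing or partial calls
    become NaN and phasing is ignored. Multi-allelic records are rejected —
    split them upstream.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise GwasError(f"VCF {path} has no sample columns")
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    for record in vcf:
        if len(record.ALT) != 1:
            raise GwasError(
                f"multi-allelic record at {record.CHROM}:{record.POS} "
                f"(ALT={record.ALT}); split multi-allelic sites upstream"
            )
        if "GT" not in (record.FORMAT or []):
            raise GwasError(f"record at {record.CHROM}:{record.POS} has no GT field")
        dosage = np.empty(len(samples))
        for i, gt in enumerate(record.genotypes):
            alleles = gt[:-1]  # last entry is the phased flag
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                dosage[i] = np.nan
            else:
                dosage[i] = sum(1 for a in alleles if a > 0)
        variants.append(
            Variant(
                chrom=record.CHROM,
                pos=int(record.POS),
                ref=record.REF,
                alt=record.ALT[0],
                id=record.ID or f"{record.CHROM}:{record.POS}",
            )
        )
        rows.append(dosage)
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeStudy(samples=samples, variants=variants, dosages=dosages)


_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf_genotypes(study: GenotypeStudy, path: str | Path) -> Path:
    """Write a GT-only VCF 4.2 representation of the study."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    for chrom in dict.fromkeys(v.chrom for v in study.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(study.samples)
    )
    for j, v in enumerate(study.variants):
        calls = [
            "./." if math.isnan(d) else _GT_CODES[float(d)]
            for d in study.dosages[:, j]
        ]
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
            + "\t".join(calls)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def variant_filters(
    study: GenotypeStudy, maf_min: float = 0.01, missing_max: float = 0.05
) -> GenotypeStudy:
    """Quality control: keep variants with MAF >= ``maf_min`` and missing
    fraction <= ``missing_max``. The sample set is unchanged."""
    if not (0.0 <= maf_min <= 0.5):
        raise GwasError("maf_min must lie in [0, 0.5]")
    if not (0.0 <= missing_max <= 1.0):
        raise GwasError("missing_max must lie in [0, 1]")
    keep = (study.maf() >= maf_min) & (study.missing_fraction() <= missing_max)
    return study.subset_variants(keep)


# ---------------------------------------------------------------------------
# Fixed-effect meta-analysis

def meta_fixed_effect(
    estimates: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect pooling of (beta, se) pairs.

    Returns (pooled_beta, pooled_se, two-sided normal p-value).
    """
    if len(estimates) == 0:
        raise GwasError("meta-analysis requires at least one estimate")
    betas = np.array([b for b, _ in estimates], float)
    ses = np.array([s for _, s in estimates], float)
    if (ses <= 0).any() or not np.isfinite(ses).all():
        raise GwasError("all standard errors must be positive and finite")
    w = ses**-2
    pooled_beta = float(np.sum(w * betas) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    p_value = float(2.0 * norm.sf(abs(pooled_beta / pooled_se)))
    return pooled_beta, pooled_se, p_value


# ---------------------------------------------------------------------------
# Result rows

@dataclass
class SNPAssociationRow:
    variant: Variant
    beta: float
    se: float
    p_value: float
    n_used: int
    maf: float
    status: str  # ok | non_converged | filtered | blocked

    def to_dict(self) -> dict:
        return {
            "chrom": self.variant.chrom,
            "pos": self.variant.pos,
            "id": self.variant.id,
            "beta": self.beta,
            "se": self.se,
            "p": self.p_value,
            "n": self.n_used,
            "maf": self.maf,
            "status": self.status,
        }


@dataclass
class MetaAnalysisRow:
    variant: Variant
    pooled_beta: float
    pooled_se: float
    p_value: float
    k_studies: int
    n_total: int
    maf: float

    # uniform column view shared with the per-SNP rows
    def to_dict(self) -> dict:
        return {
            "chrom": self.variant.chrom,
            "pos": self.variant.pos,
            "id": self.variant.id,
            "beta": self.pooled_beta,
            "se": self.pooled_se,
            "p": self.p_value,
            "n": self.n_total,
            "maf": self.maf,
            "status": "ok",
            "k": self.k_studies,
        }


def results_to_frame(rows: Sequence) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def write_results(rows: Sequence, path: str | Path) -> Path:
    path = Path(path)
    results_to_frame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Server-side operations

def _get_study(node, symbol: str) -> GenotypeStudy:
    data = node.get_dataset(symbol)
    if not isinstance(data, GenotypeStudy):
        raise GwasError(f"symbol {symbol!r} is not a genotype study")
    return data


def _geno_base(node, geno_symbol: str, pheno_symbol: str, spec: GLMSpec):
    """Phenotype design aligned to genotype sample order, cached per node.

    The phenotype table must carry a ``sample_id`` column matching the
    study's sample ids; rows without a genotype sample are dropped, as are
    phenotype-incomplete rows.
    """
    key = ("geno_base", geno_symbol, pheno_symbol, spec.formula, spec.family)
    if key in node._cache:
        return node._cache[key]
    study = _get_study(node, geno_symbol)
    pheno = node.get_dataset(pheno_symbol)
    if not isinstance(pheno, pd.DataFrame) or "sample_id" not in pheno.columns:
        raise GwasError(
            f"symbol {pheno_symbol!r} must be a phenotype table with a "
            "'sample_id' column"
        )
    sample_pos = {s: i for i, s in enumerate(study.samples)}
    matched = pheno[pheno["sample_id"].isin(sample_pos)].reset_index(drop=True)
    y, X, names = design_matrix(matched, spec)
    # design_matrix drops incomplete rows; recover which ids survived
    outcome, covariates, _ = spec.parse_formula()
    complete = matched[[outcome, *covariates]].notna().all(axis=1)
    ids = matched.loc[complete, "sample_id"]
    geno_rows = np.array([sample_pos[s] for s in ids])
    value = (y, X, names, geno_rows, study)
    node._cache[key] = value
    return value


def _variant_design(base, variant: int):
    y, X, names, geno_rows, study = base
    dosage = study.dosages[geno_rows, variant]
    mask = np.isfinite(dosage)
    Xv = np.column_stack([X[mask], dosage[mask]])
    return y[mask], Xv, (*names, "dosage")


@server_op("variant_list")
def _op_variant_list(node, symbol: str):
    study = _get_study(node, symbol)
    ids = study.variant_ids
    return ids, GuardContext(n_obs=len(study.samples), n_params=len(ids))


@server_op("geno_qc")
def _op_geno_qc(node, symbol: str):
    """Per-variant allele and missingness tallies for pooled QC."""
    study = _get_study(node, symbol)
    called = np.isfinite(study.dosages)
    payload = {
        "alt_counts": np.nansum(study.dosages, axis=0).tolist(),
        "called": called.sum(axis=0).tolist(),
        "missing": (~called).sum(axis=0).tolist(),
        "n_samples": len(study.samples),
    }
    return payload, GuardContext(
        n_obs=len(study.samples), n_params=len(study.variants)
    )


@server_op("geno_glm_step")
def _op_geno_glm_step(
    node,
    geno_symbol: str,
    pheno_symbol: str,
    spec: Mapping,
    beta: Sequence[float],
    variant: int,
):
    """One IRLS iteration share for the covariate design augmented with one
    variant's dosage column (complete-case on phenotype and dosage)."""
    glm_spec = GLMSpec.from_dict(spec)
    base = _geno_base(node, geno_symbol, pheno_symbol, glm_spec)
    y, X, names = _variant_design(base, int(variant))
    contrib = glm_server_contribution(node, glm_spec, y, X, np.asarray(beta, float))
    payload = {
        "information": contrib["information"].tolist(),
        "score_cross": contrib["score_cross"].tolist(),
        "n_obs": contrib["n_obs"],
        "deviance": contrib["deviance"],
    }
    return payload, GuardContext(n_obs=len(y), n_params=len(names))


@server_op("local_gwas")
def _op_local_gwas(
    node,
    geno_symbol: str,
    pheno_symbol: str,
    spec: Mapping,
    keep: Sequence[int],
):
    """Independent per-node scan over the kept variants. The payload per
    variant is only (beta, se, n, status) for the dosage term — one network
    round for the whole scan."""
    from .disclosure import check_model_validity

    glm_spec = GLMSpec.from_dict(spec)
    base = _geno_base(node, geno_symbol, pheno_symbol, glm_spec)
    betas, ses, ns, statuses = [], [], [], []
    for variant in keep:
        y, X, _ = _variant_design(base, int(variant))
        verdict = check_model_validity(len(y), X.shape[1], node.disclosure)
        if not verdict.allowed:
            betas.append(None); ses.append(None); ns.append(int(len(y)))
            statuses.append("blocked")
            continue
        try:
            res = fit_irls(y, X, glm_spec.family, glm_spec.max_iterations, glm_spec.tolerance)
        except GLMError:
            betas.append(None); ses.append(None); ns.append(int(len(y)))
            statuses.append("non_converged")
            continue
        betas.append(float(res["coefficients"][-1]))
        ses.append(float(res["standard_errors"][-1]))
        ns.append(int(res["n_obs"]))
        statuses.append("ok" if res["converged"] else "non_converged")
    payload = {"beta": betas, "se": ses, "n": ns, "status": statuses}
    n_obs = len(base[0])
    return payload, GuardContext(n_obs=n_obs, n_params=len(keep))


# ---------------------------------------------------------------------------
# Client-side scan

def gwas_scan(
    session: ClientSession,
    spec: GLMSpec,
    mode: str = "federated",
    maf_min: float = 0.01,
    missing_max: float = 0.05,
    geno_symbol: str = "G",
    pheno_symbol: str = "P",
) -> list:
    """Genome-wide scan across the session's nodes.

    ``spec`` is the covariate model without the genotype term; the dosage
    column is appended server-side per variant. Requires identical variant
    lists on every node. Returns :class:`SNPAssociationRow` objects in
    variant order (``federated`` mode, every variant with a status) or
    :class:`MetaAnalysisRow` objects for the variants surviving QC with at
    least one contributing study (``meta`` mode).
    """
    if mode not in ("federated", "meta"):
        raise GwasError(f"mode must be 'federated' or 'meta', got {mode!r}")

    id_resp = session.broadcast("variant_list", {"symbol": geno_symbol})
    _raise_on_block(id_resp)
    ids = id_resp[0].payload
    for resp in id_resp[1:]:
        if resp.payload != ids:
            raise GwasError(
                "variant lists are not harmonised across nodes: "
                f"{resp.node_name!r} differs from {id_resp[0].node_name!r}"
            )

    qc_resp = session.broadcast("geno_qc", {"symbol": geno_symbol})
    _raise_on_block(qc_resp)
    alt = np.zeros(len(ids))
    called = np.zeros(len(ids))
    missing = np.zeros(len(ids))
    n_samples = 0
    for resp in qc_resp:
        alt += np.asarray(resp.payload["alt_counts"], float)
        called += np.asarray(resp.payload["called"], float)
        missing += np.asarray(resp.payload["missing"], float)
        n_samples += int(resp.payload["n_samples"])
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, alt / (2.0 * called), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    miss_frac = missing / max(n_samples, 1)
    keep = (maf >= maf_min) & (miss_frac <= missing_max)

    variants = _session_variants(session, geno_symbol, ids)

    if mode == "federated":
        return _scan_federated(
            session, spec, variants, keep, maf, geno_symbol, pheno_symbol
        )
    return _scan_meta(session, spec, variants, keep, maf, geno_symbol, pheno_symbol)


def _session_variants(session, geno_symbol, ids) -> list[Variant]:
    # Variant coordinates are metadata, not individual-level data; take them
    # from the first node's study (lists are already checked identical).
    study = session.nodes[0].get_dataset(geno_symbol)
    return list(study.variants)


def _scan_federated(session, spec, variants, keep, maf, geno_symbol, pheno_symbol):
    spec_dict = spec.to_dict()
    col_resp = session.broadcast(
        "glm_columns", {"symbol": pheno_symbol, "spec": spec_dict}
    )
    _raise_on_block(col_resp)
    p = len(col_resp[0].payload["columns"]) + 1  # + dosage term
    rows: list[SNPAssociationRow] = []
    for j, variant in enumerate(variants):
        if not keep[j]:
            rows.append(
                SNPAssociationRow(variant, np.nan, np.nan, np.nan, 0, float(maf[j]), "filtered")
            )
            continue
        args = {
            "geno_symbol": geno_symbol,
            "pheno_symbol": pheno_symbol,
            "spec": spec_dict,
            "variant": int(j),
        }
        try:
            res = _federated_irls(session, spec, "geno_glm_step", args, p)
        except FederatedBlockedError:
            rows.append(
                SNPAssociationRow(variant, np.nan, np.nan, np.nan, 0, float(maf[j]), "blocked")
            )
            continue
        except GLMError:
            rows.append(
                SNPAssociationRow(variant, np.nan, np.nan, np.nan, 0, float(maf[j]), "non_converged")
            )
            continue
        beta = float(res["coefficients"][-1])
        se = float(res["standard_errors"][-1])
        status = "ok" if res["converged"] else "non_converged"
        if status != "ok":
            rows.append(
                SNPAssociationRow(variant, np.nan, np.nan, np.nan, 0, float(maf[j]), status)
            )
            continue
        p_value = float(2.0 * norm.sf(abs(beta / se)))
        rows.append(
            SNPAssociationRow(
                variant, beta, se, p_value, int(res["n_total"]), float(maf[j]), "ok"
            )
        )
    return rows


def _scan_meta(session, spec, variants, keep, maf, geno_symbol, pheno_symbol):
    keep_idx = [int(i) for i in np.flatnonzero(keep)]
    responses = session.broadcast(
        "local_gwas",
        {
            "geno_symbol": geno_symbol,
            "pheno_symbol": pheno_symbol,
            "spec": spec.to_dict(),
            "keep": keep_idx,
        },
    )
    _raise_on_block(responses)
    rows: list[MetaAnalysisRow] = []
    for pos, j in enumerate(keep_idx):
        estimates = []
        n_total = 0
        for resp in responses:
            if resp.payload["status"][pos] == "ok":
                estimates.append(
                    (resp.payload["beta"][pos], resp.payload["se"][pos])
                )
                n_total += int(resp.payload["n"][pos])
        if not estimates:
            continue
        pooled_beta, pooled_se, p_value = meta_fixed_effect(estimates)
        rows.append(
            MetaAnalysisRow(
                variant=variants[j],
                pooled_beta=pooled_beta,
                pooled_se=pooled_se,
                p_value=p_value,
                k_studies=len(estimates),
                n_total=n_total,
                maf=float(maf[j]),
            )
        )
    return rows
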