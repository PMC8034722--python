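"""Seeded generators of multi-node studies with known ground truth.

Every workflow in the package (tabular federated GLM, two-mode GWAS, GPS
exposure analysis) has a generator here producing hermetic, deterministic
inputs whose true parameters are recorded in a :class:`StudyTruth`, so
end-to-end tests can check parameter recovery. Fixture writers render the
studies in the external formats (CSV, VCF 4.2 with GT-only FORMAT, resource
descriptors, node configs) so a demo session can be assembled purely from
files.

Generator defaults define the study conditions: tabular covariates are
standard normal or Bernoulli(0.5); genotypes are drawn in Hardy-Weinberg
proportions at each variant's allele frequency; the geospatial study
defaults to 810 individuals and 6100 outlets in a 10 km square with commute
traces modelled as noisy home-to-work polylines.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .disclosure import DisclosureConfig
from .geo import OutletSet, TraceSet, buffer_points, trace_exposure_counts
from .gwas import GenotypeStudy, Variant, write_vcf_genotypes
from .resources import ResourceDescriptor, file_url


@dataclass(frozen=True)
class StudyTruth:
    """Ground truth fully determining a generated study given the seed."""

    seed: int = 0
    family: str = "gaussian"
    # tabular model
    intercept: float = 0.5
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"x1": 1.0, "x2": 0.5, "bin1": -0.5}
    )
    covariate_kinds: Mapping[str, str] = field(
        default_factory=lambda: {"x1": "normal", "x2": "normal", "bin1": "binary"}
    )
    noise_sd: float = 1.0
    # genomic
    n_variants: int = 200
    causal_effects: Mapping[str, float] = field(default_factory=dict)
    causal_maf: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    geno_missing_rate: float = 0.0
    # geospatial
    n_individuals: int = 810
    n_outlets: int = 6100
    area: float = 10_000.0  # side of the square study region, metres
    radius: float = 50.0  # buffer radius, metres
    exposure_effect: float = 0.05  # outcome units per distinct buffer
    geo_noise_sd: float = 3.0
    geo_covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.05,
            "sex": 0.5,
            "income": -0.3,
            "education[mid]": -0.2,
            "education[high]": -0.5,
            "smoking": 0.3,
        }
    )

    def true_vector(self) -> dict[str, float]:
        out = {"(Intercept)": self.intercept}
        out.update(self.coefficients)
        return out


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


# ---------------------------------------------------------------------------
# Tabular studies

def _linear_predictor(truth: StudyTruth, covs: dict[str, np.ndarray]) -> np.ndarray:
    eta = np.full(len(next(iter(covs.values()))), truth.intercept)
    for name, beta in truth.coefficients.items():
        eta = eta + beta * covs[name]
    return eta


def _draw_outcome(family: str, eta: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    if family == "gaussian":
        return eta + rng.normal(0.0, noise_sd, len(eta))
    if family == "binomial":
        return rng.binomial(1, expit(eta)).astype(float)
    if family == "poisson":
        return rng.poisson(np.exp(np.clip(eta, -30, 30))).astype(float)
    raise ValueError(f"unknown family {family!r}")


def gen_tabular_study(
    n_per_node: Sequence[int], truth: StudyTruth
) -> list[pd.DataFrame]:
    """One data frame per node with covariates and outcome ``y`` drawn from
    the truth's GLM at the stated coefficients."""
    if any(n < 1 for n in n_per_node):
        raise ValueError("node sizes must be >= 1")
    tables = []
    for k, n in enumerate(n_per_node):
        rng = _rng(truth.seed, 101, k)
        covs = {}
        for name in truth.coefficients:
            kind = truth.covariate_kinds.get(name, "normal")
            if kind == "binary":
                covs[name] = rng.binomial(1, 0.5, n).astype(float)
            else:
                covs[name] = rng.normal(0.0, 1.0, n)
        eta = _linear_predictor(truth, covs)
        y = _draw_outcome(truth.family, eta, truth.noise_sd, rng)
        tables.append(pd.DataFrame({**covs, "y": y}))
    return tables


# ---------------------------------------------------------------------------
# Genotype studies

def default_genotype_truth(
    seed: int = 0,
    n_variants: int = 200,
    n_causal: int = 5,
    effect: float = 0.4,
    family: str = "gaussian",
) -> StudyTruth:
    """Causal variants spread evenly through the variant list at the stated
    effect size (paper-scale per-allele effect on a unit-variance trait)."""
    step = max(n_variants // max(n_causal, 1), 1)
    causal = {f"rs{j * step + 1}": effect for j in range(n_causal)}
    return StudyTruth(
        seed=seed, family=family, n_variants=n_variants, causal_effects=causal
    )


def gen_genotype_study(
    n_per_node: Sequence[int], n_variants: int, truth: StudyTruth
) -> list[tuple[GenotypeStudy, pd.DataFrame]]:
    """Per node: a GenotypeStudy in Hardy-Weinberg proportions plus a
    phenotype table (``sample_id``, ``y``) with the trait built from the
    causal dosages. Variant lists (and their allele frequencies) are shared
    across nodes."""
    rng_global = _rng(truth.seed, 202)
    mafs = rng_global.uniform(*truth.maf_range, n_variants)
    variants = [
        Variant(chrom="1", pos=(j + 1) * 1000, ref="A", alt="G", id=f"rs{j + 1}")
        for j in range(n_variants)
    ]
    id_to_col = {v.id: j for j, v in enumerate(variants)}
    for vid in truth.causal_effects:
        if vid not in id_to_col:
            raise ValueError(f"causal variant {vid!r} not in the variant list")
        mafs[id_to_col[vid]] = truth.causal_maf

    out = []
    for k, n in enumerate(n_per_node):
        rng = _rng(truth.seed, 203, k)
        dosages = rng.binomial(2, mafs, size=(n, n_variants)).astype(float)
        if truth.geno_missing_rate > 0:
            mask = rng.random((n, n_variants)) < truth.geno_missing_rate
            dosages[mask] = np.nan
        samples = [f"N{k}S{i}" for i in range(n)]
        eta = np.full(n, truth.intercept)
        for vid, effect in truth.causal_effects.items():
            d = dosages[:, id_to_col[vid]]
            eta = eta + effect * np.nan_to_num(d, nan=2.0 * mafs[id_to_col[vid]])
        y = _draw_outcome(truth.family, eta, truth.noise_sd, rng)
        study = GenotypeStudy(samples=samples, variants=list(variants), dosages=dosages)
        out.append((study, pd.DataFrame({"sample_id": samples, "y": y})))
    return out


# ---------------------------------------------------------------------------
# Geospatial studies

def gen_geo_study(
    n_individuals: int | None = None,
    n_outlets: int | None = None,
    truth: StudyTruth | None = None,
) -> tuple[OutletSet, TraceSet, pd.DataFrame]:
    """Outlets on a jittered grid, commute traces as noisy home-to-work
    polylines, and a phenotype table whose BMI carries the stated exposure
    effect (computed from the true buffer intersections) plus covariate
    effects and noise."""
    truth = truth or StudyTruth()
    n_ind = n_individuals if n_individuals is not None else truth.n_individuals
    n_out = n_outlets if n_outlets is not None else truth.n_outlets

    rng = _rng(truth.seed, 301)
    side = int(np.ceil(np.sqrt(n_out)))
    spacing = truth.area / side
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    centres = np.column_stack([gx.ravel(), gy.ravel()])[:n_out] * spacing + spacing / 2
    jitter = rng.uniform(-0.3, 0.3, size=centres.shape) * spacing
    outlets = OutletSet(
        ids=[f"o{i}" for i in range(n_out)], coords=centres + jitter
    )

    n_vertices = 12
    t = np.linspace(0.0, 1.0, n_vertices)
    traces = {}
    for i in range(n_ind):
        r = _rng(truth.seed, 302, i)
        home = r.uniform(0, truth.area, 2)
        work = r.uniform(0, truth.area, 2)
        walk = np.cumsum(r.normal(0.0, 80.0, (n_vertices, 2)), axis=0)
        bridge = walk - t[:, None] * walk[-1]  # endpoints stay at home/work
        traces[f"p{i}"] = home + t[:, None] * (work - home) + bridge
    trace_set = TraceSet(traces)

    exposure = trace_exposure_counts(
        trace_set, buffer_points(outlets, truth.radius, 64)
    )
    ids = [f"p{i}" for i in range(n_ind)]
    exp_counts = exposure.loc[ids].to_numpy(float)

    rng_ph = _rng(truth.seed, 303)
    age = rng_ph.normal(45.0, 10.0, n_ind)
    sex = rng_ph.binomial(1, 0.5, n_ind).astype(float)
    income = rng_ph.normal(0.0, 1.0, n_ind)
    education = rng_ph.choice(["low", "mid", "high"], n_ind, p=[0.3, 0.4, 0.3])
    smoking = rng_ph.binomial(1, 0.3, n_ind).astype(float)
    eff = truth.geo_covariate_effects
    bmi = (
        25.0
        + truth.exposure_effect * exp_counts
        + eff.get("age", 0.0) * (age - 45.0)
        + eff.get("sex", 0.0) * sex
        + eff.get("income", 0.0) * income
        + eff.get("education[mid]", 0.0) * (education == "mid")
        + eff.get("education[high]", 0.0) * (education == "high")
        + eff.get("smoking", 0.0) * smoking
        + rng_ph.normal(0.0, truth.geo_noise_sd, n_ind)
    )
    pheno = pd.DataFrame(
        {
            "id": ids,
            "bmi": bmi,
            "age": age,
            "sex": sex,
            "income": income,
            "education": education,
            "smoking": smoking,
        }
    )
    return outlets, trace_set, pheno


def split_geo_study(
    outlets: OutletSet,
    traces: TraceSet,
    pheno: pd.DataFrame,
    node_sizes: Sequence[int],
) -> list[tuple[OutletSet, TraceSet, pd.DataFrame]]:
    """Partition individuals over nodes (outlets are shared context)."""
    ids = list(pheno["id"])
    if sum(node_sizes) != len(ids):
        raise ValueError("node sizes must sum to the number of individuals")
    out = []
    start = 0
    for n in node_sizes:
        chunk = ids[start : start + n]
        out.append(
            (
                outlets,
                TraceSet({i: traces.traces[i] for i in chunk}),
                pheno[pheno["id"].isin(chunk)].reset_index(drop=True),
            )
        )
        start += n
    return out


# ---------------------------------------------------------------------------
# Fixture writers

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(directory: Path, files: Sequence[Path]) -> dict[str, str]:
    manifest = {str(f.relative_to(directory)): _sha256(f) for f in sorted(files)}
    lines = [f"{digest}  {name}" for name, digest in manifest.items()]
    (directory / "manifest.txt").write_text("\n".join(lines) + "\n")
    return manifest


def _node_config(
    directory: Path,
    node_name: str,
    resources: dict[str, ResourceDescriptor],
    disclosure: DisclosureConfig,
) -> Path:
    config = {
        "node_name": node_name,
        "resources": {name: d.to_dict() for name, d in resources.items()},
        "disclosure": disclosure.to_dict(),
    }
    path = directory / f"{node_name}.yaml"
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def write_tabular_fixtures(
    tables: Sequence[pd.DataFrame],
    directory: str | Path,
    disclosure: DisclosureConfig | None = None,
) -> dict[str, str]:
    """One CSV + descriptor + node config per node, plus a digest manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    disclosure = disclosure or DisclosureConfig()
    files = []
    for k, table in enumerate(tables):
        name = f"study{k}"
        csv_path = directory / f"{name}_data.csv"
        table.to_csv(csv_path, index=False)
        descriptor = ResourceDescriptor(
            url=file_url(csv_path),
            format="csv",
            name=f"{name}-data",
            identity="analyst",
            secret=f"tok-{name}",
        )
        files.append(csv_path)
        files.append(_node_config(directory, name, {"data": descriptor}, disclosure))
    return _write_manifest(directory, files)


def write_genotype_fixtures(
    studies: Sequence[tuple[GenotypeStudy, pd.DataFrame]],
    directory: str | Path,
    disclosure: DisclosureConfig | None = None,
) -> dict[str, str]:
    """Per node: a GT-only VCF, a phenotype CSV, descriptors and node config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    disclosure = disclosure or DisclosureConfig()
    files = []
    for k, (study, pheno) in enumerate(studies):
        name = f"study{k}"
        vcf_path = write_vcf_genotypes(study, directory / f"{name}_geno.vcf")
        csv_path = directory / f"{name}_pheno.csv"
        pheno.to_csv(csv_path, index=False)
        resources = {
            "genotypes": ResourceDescriptor(
                url=file_url(vcf_path), format="vcf", name=f"{name}-genotypes",
                identity="analyst", secret=f"tok-{name}",
            ),
            "phenotypes": ResourceDescriptor(
                url=file_url(csv_path), format="csv", name=f"{name}-phenotypes",
            ),
        }
        files += [vcf_path, csv_path, _node_config(directory, name, resources, disclosure)]
    return _write_manifest(directory, files)


def write_geo_fixtures(
    node_studies: Sequence[tuple[OutletSet, TraceSet, pd.DataFrame]],
    directory: str | Path,
    disclosure: DisclosureConfig | None = None,
) -> dict[str, str]:
    """Per node: outlets CSV (id,x,y), traces CSV (id,seq,x,y), phenotype
    CSV, descriptors and node config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    disclosure = disclosure or DisclosureConfig()
    files = []
    for k, (outlets, traces, pheno) in enumerate(node_studies):
        name = f"study{k}"
        paths = {
            "outlets": directory / f"{name}_outlets.csv",
            "traces": directory / f"{name}_traces.csv",
            "pheno": directory / f"{name}_pheno.csv",
        }
        outlets.to_frame().to_csv(paths["outlets"], index=False)
        traces.to_frame().to_csv(paths["traces"], index=False)
        pheno.to_csv(paths["pheno"], index=False)
        resources = {
            rname: ResourceDescriptor(
                url=file_url(p), format="csv", name=f"{name}-{rname}"
            )
            for rname, p in paths.items()
        }
        files += list(paths.values())
        files.append(_node_config(directory, name, resources, disclosure))
    return _write_manifest(directory, files)


def write_fixtures(study, directory: str | Path, **kwargs) -> dict[str, str]:
    """Dispatch on the generated study type and write its fixture files."""
    if isinstance(study, Sequence) and study and isinstance(study[0], pd.DataFrame):
        return write_tabular_fixtures(study, directory, **kwargs)
    if (
        isinstance(study, Sequence)
        and study
        and isinstance(study[0], tuple)
        and isinstance(study[0][0], GenotypeStudy)
    ):
        return write_genotype_fixtures(study, directory, **kwargs)
    if (
        isinstance(study, Sequence)
        and study
        and isinstance(study[0], tuple)
        and isinstance(study[0][0], OutletSet)
    ):
        return write_geo_fixtures(study, directory, **kwargs)
    raise TypeError("unrecognised study structure for fixture writing")
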