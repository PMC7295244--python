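"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator plants, inside each coarse co-expression module, several tight
submodules driven by latent factors, plus weakly loading noise genes. Factors
optionally carry a single-SNP QTL effect and case-subtype mean shifts;
genotypes come from a two-population Balding-Nichols model so that kinship
correction is genuinely necessary downstream. Ground truth (memberships,
factors, QTLs, subtype and population labels) is recorded for recovery
scoring.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, write_covariates, write_expression, write_module_assignment, write_vcf

# WGCNA-style colour labels for coarse modules
_MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple",
)


@dataclass
class CohortSpec:
    """Generator parameters; defaults emulate the study conditions.

    ~300 decedents with roughly one third cases, two ancestral populations at
    F_st = 0.1, four coarse modules each holding two planted submodules of 60
    genes plus ~10% weakly correlated noise genes, gene loadings U(0.5, 0.9),
    one eigengene-QTL per submodule explaining 15% of factor variance, and
    two case subtypes whose eigengene means shift diametrically with centroid
    separation ``subtype_shift`` within-cluster SDs.
    """

    n_samples: int = 300
    case_fraction: float = 1 / 3
    other_fraction: float = 0.2
    n_populations: int = 2
    f_st: float = 0.1
    n_variants: int = 500
    n_modules: int = 4
    submodules_per_module: int = 2
    genes_per_submodule: int = 60
    noise_gene_fraction: float = 0.1
    loading_range: tuple[float, float] = (0.5, 0.9)
    noise_loading_max: float = 0.2
    qtl_variance_explained: float = 0.15
    n_subtypes: int = 2
    subtype_shift: float = 2.0
    sex_effect: float = 0.2
    age_effect: float = 0.01
    batch_effect: float = 0.2
    n_batches: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("case_fraction", "other_fraction", "noise_gene_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.case_fraction + self.other_fraction > 1:
            raise ValueError("case_fraction + other_fraction exceeds 1")
        if not 0 <= self.qtl_variance_explained < 1:
            raise ValueError("qtl_variance_explained must be in [0,1)")
        if self.n_subtypes < 2:
            raise ValueError("n_subtypes must be >= 2")
        if not 0 <= self.f_st < 1:
            raise ValueError("f_st must be in [0,1)")

    @property
    def n_submodules(self) -> int:
        return self.n_modules * self.submodules_per_module

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "loading_range" in kwargs:
            kwargs["loading_range"] = tuple(kwargs["loading_range"])
        return cls(**kwargs)


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery scoring."""

    submodule_membership: dict[str, tuple[str, object]]  # gene -> (module, idx|"noise")
    factors: pd.DataFrame  # submodules x samples
    qtls: list[dict]  # {variant_id, submodule, beta}
    subtype_labels: dict[str, str]  # case sample -> "A"/"B"/...
    population_labels: dict[str, str]
    f_st: float
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "submodule_membership": {
                g: list(v) for g, v in self.submodule_membership.items()
            },
            "factors": {
                "index": list(self.factors.index),
                "columns": list(self.factors.columns),
                "values": self.factors.values.tolist(),
            },
            "qtls": self.qtls,
            "subtype_labels": self.subtype_labels,
            "population_labels": self.population_labels,
            "f_st": self.f_st,
            "params": self.params,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        factors = pd.DataFrame(
            raw["factors"]["values"],
            index=raw["factors"]["index"],
            columns=raw["factors"]["columns"],
        )
        return cls(
            submodule_membership={
                g: tuple(v) for g, v in raw["submodule_membership"].items()
            },
            factors=factors,
            qtls=raw["qtls"],
            subtype_labels=raw["subtype_labels"],
            population_labels=raw["population_labels"],
            f_st=raw["f_st"],
            params=raw["params"],
            seed=raw["seed"],
        )


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def simulate_genotypes(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Balding-Nichols genotypes for ``n_populations`` populations.

    Ancestral frequencies are U(0.1, 0.5); each population draws its own
    frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with F = F_st (for F_st = 0
    the ancestral frequency is used directly); genotypes are Binomial(2, .).
    Returns the dosage matrix and the centered GRM of the generated dosages
    as the true kinship.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, m = spec.n_samples, spec.n_variants
    pop = np.repeat(np.arange(spec.n_populations), -(-n // spec.n_populations))[:n]
    p_anc = rng.uniform(0.1, 0.5, size=m)
    if spec.f_st > 0 and spec.n_populations > 1:
        c = (1 - spec.f_st) / spec.f_st
        p_pop = rng.beta(
            np.outer(np.ones(spec.n_populations), p_anc * c),
            np.outer(np.ones(spec.n_populations), (1 - p_anc) * c),
        )
    else:
        p_pop = np.tile(p_anc, (spec.n_populations, 1))
    p_pop = np.clip(p_pop, 1e-6, 1 - 1e-6)
    dosages = rng.binomial(2, p_pop[pop, :]).astype(float)

    # variants laid out on 4 chromosomes, 10 kb spacing
    per_chrom = -(-m // 4)
    meta = []
    for j in range(m):
        chrom = str(j // per_chrom + 1)
        pos = (j % per_chrom) * 10_000 + 10_000
        meta.append((chrom, pos, "A", "G", f"rs{j + 1:06d}", False))
    variants = pd.DataFrame(
        meta, columns=["chrom", "pos", "ref", "alt", "id", "imputed"]
    )
    geno = GenotypeMatrix(dosages, variants, _sample_ids(n))

    phat = dosages.mean(axis=0) / 2.0
    keep = (phat > 0) & (phat < 1)
    Z = (dosages[:, keep] - 2 * phat[keep]) / np.sqrt(
        2 * phat[keep] * (1 - phat[keep])
    )
    kinship = Z @ Z.T / keep.sum()
    return geno, kinship


def _subtype_centroids(spec: CohortSpec) -> np.ndarray:
    """Subtype mean-shift patterns in factor space (K x n_submodules).

    Shifts live in the span of the first two submodule factors, scaled so the
    minimum pairwise centroid distance equals ``subtype_shift`` within-cluster
    (residual) SDs. K=2 gives the diametric +/- pattern of the study.
    """
    K, S = spec.n_subtypes, spec.n_submodules
    centroids = np.zeros((K, S))
    if spec.subtype_shift == 0:
        return centroids
    if S < 2:
        raise ValueError("need at least 2 submodules for subtype structure")
    if K == 2:
        r = spec.subtype_shift / 2.0
        u = np.array([1.0, -1.0]) / np.sqrt(2)
        centroids[0, :2] = r * u
        centroids[1, :2] = -r * u
    else:
        theta = 2 * np.pi * np.arange(K) / K
        # circle radius giving nearest-neighbour distance = subtype_shift
        r = spec.subtype_shift / (2 * np.sin(np.pi / K))
        centroids[:, 0] = r * np.cos(theta)
        centroids[:, 1] = r * np.sin(theta)
    return centroids


def structured_null_trait(
    genotypes: GenotypeMatrix,
    population: np.ndarray,
    h2: float = 0.4,
    pop_shift: float = 0.5,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """A null trait confounded by structure but linked to no single variant.

    The trait is a within-population polygenic component (drawn from the
    standardized dosages, population means removed so the confounding
    magnitude is exactly ``pop_shift``) at heritability ``h2``, plus a mean
    shift of ``pop_shift`` residual SDs for the second population, plus
    noise. Uncorrected per-variant OLS scans of this trait inflate; a mixed
    model with kinship from the same genotypes should calibrate.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    G = genotypes.dosages
    p = G.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    Z = (G[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    u = Z @ rng.standard_normal(keep.sum()) / np.sqrt(keep.sum())
    for lab in np.unique(population):  # keep only within-population relatedness
        u[population == lab] -= u[population == lab].mean()
    u = u / u.std(ddof=0)
    e = rng.standard_normal(G.shape[0])
    y = np.sqrt(h2) * u + np.sqrt(1 - h2) * e
    y = y + pop_shift * (population == np.unique(population)[-1])
    return y


def population_vector(spec: CohortSpec) -> np.ndarray:
    """Population index per sample, matching simulate_genotypes' layout."""
    return np.repeat(
        np.arange(spec.n_populations), -(-spec.n_samples // spec.n_populations)
    )[: spec.n_samples]


def simulate_expression(
    spec: CohortSpec,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, SyntheticTruth]:
    """Factor-model expression on top of the simulated genotypes.

    Each planted submodule s has a latent factor
    ``f_s = beta_q * z(QTL dosage) + subtype shift + residual`` standardized
    to unit variance, with ``beta_q`` set so the QTL explains
    ``qtl_variance_explained`` of the factor variance. Member genes load
    lambda ~ U(loading_range); noise genes load at most ``noise_loading_max``.
    Sex, age-at-death and batch effects are added additively to every gene.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    n = spec.n_samples
    samples = list(genotypes.sample_ids)
    pop = np.repeat(
        np.arange(spec.n_populations), -(-n // spec.n_populations)
    )[:n]

    # diagnoses: cases first third (shuffled), then OTHER, then CONTROL
    n_case = int(round(spec.case_fraction * n))
    n_other = int(round(spec.other_fraction * n))
    diag = np.array(
        ["CASE"] * n_case + ["OTHER"] * n_other + ["CONTROL"] * (n - n_case - n_other)
    )
    rng.shuffle(diag)
    case_idx = np.where(diag == "CASE")[0]

    # subtype assignment among cases
    subtype_names = [chr(ord("A") + k) for k in range(spec.n_subtypes)]
    sub_assign = rng.integers(0, spec.n_subtypes, size=len(case_idx))
    centroids = _subtype_centroids(spec)

    # one QTL variant per submodule, sampled without replacement
    S = spec.n_submodules
    if S > genotypes.n_variants:
        raise ValueError("more QTLs requested than variants available")
    qtl_idx = rng.choice(genotypes.n_variants, size=S, replace=False)

    factors = np.zeros((S, n))
    qtls = []
    v = spec.qtl_variance_explained
    sub_labels = []
    module_names = [
        _MODULE_COLORS[i % len(_MODULE_COLORS)] for i in range(spec.n_modules)
    ]
    for s in range(S):
        mod = s // spec.submodules_per_module
        sub_labels.append((module_names[mod], s % spec.submodules_per_module))
        resid = rng.standard_normal(n)
        if v > 0:
            g = genotypes.dosages[:, qtl_idx[s]]
            z = (g - g.mean()) / g.std(ddof=0)
            # orthonormalize the residual against z so the QTL share of the
            # (pre-shift) factor variance is exactly v in this realization
            e = resid - (z @ resid / n) * z
            e = (e - e.mean()) / e.std(ddof=0)
            base = np.sqrt(v) * z + np.sqrt(1 - v) * e
            qtls.append(
                {
                    "variant_id": str(genotypes.variants.iloc[qtl_idx[s]]["id"]),
                    "submodule": s,
                    "beta": float(np.sqrt(v)),
                }
            )
        else:
            base = resid
        # subtype shifts are expressed in within-cluster (base) SD units
        shift = np.zeros(n)
        shift[case_idx] = centroids[sub_assign, s]
        f = base + base.std(ddof=0) * shift
        factors[s] = (f - f.mean()) / f.std(ddof=0)

    # genes: members then per-module noise genes
    lo, hi = spec.loading_range
    gene_rows, gene_ids, membership = [], [], {}
    gid = 0
    module_of_gene = {}
    for mod in range(spec.n_modules):
        subs = range(
            mod * spec.submodules_per_module, (mod + 1) * spec.submodules_per_module
        )
        for s in subs:
            for _ in range(spec.genes_per_submodule):
                gid += 1
                gene = f"G{gid:05d}"
                lam = rng.uniform(lo, hi)
                x = lam * factors[s] + np.sqrt(1 - lam**2) * rng.standard_normal(n)
                gene_rows.append(x)
                gene_ids.append(gene)
                membership[gene] = (module_names[mod], s % spec.submodules_per_module)
                module_of_gene[gene] = module_names[mod]
        n_noise = int(round(
            spec.noise_gene_fraction
            * spec.submodules_per_module
            * spec.genes_per_submodule
        ))
        for _ in range(n_noise):
            gid += 1
            gene = f"G{gid:05d}"
            lam = rng.uniform(0.0, spec.noise_loading_max)
            s = rng.choice(list(subs))
            x = lam * factors[s] + np.sqrt(1 - lam**2) * rng.standard_normal(n)
            gene_rows.append(x)
            gene_ids.append(gene)
            membership[gene] = (module_names[mod], "noise")
            module_of_gene[gene] = module_names[mod]

    expr = np.asarray(gene_rows)

    # covariates and their additive effects
    sex = rng.integers(0, 2, size=n)  # 0 female, 1 male
    age = rng.normal(85.0, 6.0, size=n)
    batch = rng.integers(0, spec.n_batches, size=n)
    G = expr.shape[0]
    b_sex = rng.normal(0.0, spec.sex_effect, size=G)
    b_age = rng.normal(0.0, spec.age_effect, size=G)
    b_batch = rng.normal(0.0, spec.batch_effect, size=(G, spec.n_batches))
    expr = (
        expr
        + np.outer(b_sex, sex)
        + np.outer(b_age, age - age.mean())
        + b_batch[:, batch]
    )

    expr_df = pd.DataFrame(expr, index=gene_ids, columns=samples)
    expr_df.index.name = "gene_id"
    modules = pd.Series(
        {g: module_of_gene[g] for g in gene_ids}, name="module"
    )
    cov = pd.DataFrame(
        {
            "sex": np.where(sex == 1, "male", "female"),
            "age_death": age,
            "batch": [f"B{b + 1}" for b in batch],
            "diagnosis": diag,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = SyntheticTruth(
        submodule_membership=membership,
        factors=pd.DataFrame(
            factors,
            index=[f"{m}_{i}" for m, i in sub_labels],
            columns=samples,
        ),
        qtls=qtls,
        subtype_labels={
            samples[i]: subtype_names[k] for i, k in zip(case_idx, sub_assign)
        },
        population_labels={samples[i]: f"P{pop[i] + 1}" for i in range(n)},
        f_st=spec.f_st,
        params=dataclasses.asdict(spec),
        seed=spec.seed,
    )
    return expr_df, modules, cov, truth


def simulate_cohort(spec: CohortSpec):
    """Genotypes + expression + covariates + truth in one call."""
    geno, kinship = simulate_genotypes(spec)
    expr, modules, cov, truth = simulate_expression(spec, geno)
    return geno, kinship, expr, modules, cov, truth


def write_cohort(
    spec: CohortSpec, out_dir: str | Path, overwrite: bool = False
) -> dict[str, Path]:
    """Generate a cohort and write its five files to ``out_dir``.

    Emits expression.tsv, modules.tsv, covariates.tsv, genotypes.vcf and
    truth.json; refuses a non-empty existing directory unless ``overwrite``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    geno, _, expr, modules, cov, truth = simulate_cohort(spec)
    paths = {
        "expression": out / "expression.tsv",
        "modules": out / "modules.tsv",
        "covariates": out / "covariates.tsv",
        "genotypes": out / "genotypes.vcf",
        "truth": out / "truth.json",
    }
    write_expression(expr, paths["expression"])
    write_module_assignment(modules, paths["modules"])
    write_covariates(cov, paths["covariates"])
    write_vcf(geno, paths["genotypes"])
    truth.to_json(paths["truth"])
    return paths
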