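"""Synthetic bulk RNA-seq counts under an explicit sex-chromosome dosage model.

The generator emulates an isogenic panel of XX, XY, XXY and XO lines. Every
gene g has a log-normal baseline expression level ``mu_g`` shared by all
genotypes; what differs between genotypes is a per-gene *effective dose*
``d`` on a diploid-autosome scale (autosomes: d = 2). The model encodes:

* **X-upregulation**: the single active X produces ``u``-fold output
  (u = 2 means full compensation, so an XCI-subject X gene has d = u
  regardless of how many silent copies are present).
* **X inactivation with escape**: escapees additionally express a fraction
  ``e`` from each inactive X, d = u * (1 + e * n_inactive).
* **An XIST-like marker gene** expressed only when an inactive X exists.
* **Y genes** with d equal to the Y copy number (0 in XX/XO).
* **Erosion** (optional): loss of the XIST-like signal and full reactivation
  of XCI-subject genes on the formerly inactive X.
* **Trans effects on autosomes**: a subset of autosomal targets responds to
  the "regulator dose" r = n_Y + max(n_X - 1, 0) (XX:1, XY:1, XXY:2, XO:0)
  with d = 2 * 2**(beta * (1 - r)). This is a generator design choice built
  to reproduce the observed architecture (XX ~ XY; XO strongly deregulated,
  predominantly on autosomes), not a mechanistic claim.

Counts are negative-binomial, ``var = m + alpha * m**2``, with per-sample
library size factors; allele counts at one informative SNP per X gene are
binomial given Poisson coverage. All randomness flows from a single integer
seed through fixed, documented substreams, so identical parameters give
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError

__all__ = [
    "GENOTYPES",
    "GenotypeSpec",
    "SimulationParams",
    "build_annotation",
    "build_sample_sheet",
    "effective_dose",
    "simulate_counts",
    "simulate_allele_counts",
    "true_lfc",
]

#: Canonical genotypes: label -> (n_X, n_Y).
GENOTYPES: Mapping[str, tuple[int, int]] = {
    "XX": (2, 0),
    "XY": (1, 1),
    "XXY": (2, 1),
    "XO": (1, 0),
}

CHROM_CLASSES = ("autosome", "X", "Y")
X_CATEGORIES = ("xci_subject", "escapee", "xist_like", "none")

# Substream indices hung off the single seed (SeedSequence(seed, stream)).
_STREAM_ANNOTATION = 0
_STREAM_COUNTS = 1
_STREAM_ALLELES = 2
_STREAM_SHEET = 3


@dataclass(frozen=True)
class GenotypeSpec:
    """Sex-chromosome complement of a line, plus its erosion state."""

    genotype: str
    n_x: int
    n_y: int
    eroded: bool = False

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise InputError(f"unknown genotype label: {self.genotype!r}")
        exp_x, exp_y = GENOTYPES[self.genotype]
        if (self.n_x, self.n_y) != (exp_x, exp_y):
            raise InputError(
                f"inconsistent GenotypeSpec: {self.genotype} implies "
                f"(n_X={exp_x}, n_Y={exp_y}), got ({self.n_x}, {self.n_y})"
            )

    @classmethod
    def from_label(cls, label: str, eroded: bool = False) -> "GenotypeSpec":
        label = label.strip().upper()
        if label not in GENOTYPES:
            raise InputError(f"unknown genotype label: {label!r}")
        n_x, n_y = GENOTYPES[label]
        return cls(label, n_x, n_y, eroded)

    @property
    def regulator_dose(self) -> int:
        """r = n_Y + max(n_X - 1, 0): XX 1, XY 1, XXY 2, XO 0."""
        return self.n_y + max(self.n_x - 1, 0)


@dataclass
class SimulationParams:
    """Generative-model parameters.

    Defaults encode a desk-scale transcriptome with full X-dosage
    compensation (u = 2), partial escape (e = 0.3), no erosion, and a
    trans-target fraction of autosomal genes (~12.5%) sized so that
    X-monosomy deregulates thousands of genes, ~95% of them autosomal,
    while XX vs XY differences stay confined to Y genes and the
    XIST-like marker.
    """

    n_autosomal: int = 12000
    n_x_xci: int = 500
    n_x_escape: int = 100
    n_y: int = 25
    n_trans_targets: int = 1500
    escape_fraction: float = 0.3
    upregulation: float = 2.0
    beta_scale: float = 1.0
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05
    library_size_factors: Sequence[float] | None = None
    replicates_per_genotype: int = 3
    erosion_probability: float = 0.0
    bleed_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_autosomal", "n_x_xci", "n_x_escape", "n_y",
                     "n_trans_targets", "replicates_per_genotype"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_trans_targets > self.n_autosomal:
            raise ParameterError(
                f"n_trans_targets ({self.n_trans_targets}) exceeds "
                f"n_autosomal ({self.n_autosomal})"
            )
        if not 0.0 <= self.escape_fraction <= 1.0:
            raise ParameterError("escape_fraction must be in [0, 1]")
        if not 0.0 <= self.erosion_probability <= 1.0:
            raise ParameterError("erosion_probability must be in [0, 1]")
        if self.upregulation <= 0:
            raise ParameterError("upregulation must be > 0")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if self.beta_scale <= 0:
            raise ParameterError("beta_scale must be > 0")
        if not 0.0 <= self.bleed_fraction < 1.0:
            raise ParameterError("bleed_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["library_size_factors"] is not None:
            d["library_size_factors"] = list(d["library_size_factors"])
        return d


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((params.seed, stream)))


def build_annotation(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the gene annotation and the truth-table skeleton.

    Returns ``(annotation, truth)``. The annotation has one row per gene:
    ``gene_id, chrom_class, x_category, trans_target, trans_beta``; gene count
    is n_autosomal + n_x_xci + n_x_escape + n_y + 1 (one XIST-like gene).
    The truth skeleton carries the annotation columns plus the log-normal
    baseline ``mu``. Deterministic given ``params.seed``.
    """
    params.validate()
    rng = _rng(params, _STREAM_ANNOTATION)

    rows: list[tuple[str, str, str]] = []
    rows += [(f"AUT{i:05d}", "autosome", "none") for i in range(params.n_autosomal)]
    rows += [(f"XCI{i:04d}", "X", "xci_subject") for i in range(params.n_x_xci)]
    rows += [(f"ESC{i:04d}", "X", "escapee") for i in range(params.n_x_escape)]
    rows.append(("XIST_LIKE", "X", "xist_like"))
    rows += [(f"YLK{i:03d}", "Y", "none") for i in range(params.n_y)]

    ann = pd.DataFrame(rows, columns=["gene_id", "chrom_class", "x_category"])
    ann["trans_target"] = False
    ann["trans_beta"] = 0.0

    # Trans targets: random autosomal subset; |beta| half-normal, random sign.
    target_pos = rng.choice(params.n_autosomal, size=params.n_trans_targets,
                            replace=False)
    betas = np.abs(rng.normal(0.0, params.beta_scale, size=params.n_trans_targets))
    signs = np.where(rng.random(params.n_trans_targets) < 0.5, -1.0, 1.0)
    ann.loc[target_pos, "trans_target"] = True
    ann.loc[target_pos, "trans_beta"] = betas * signs

    mu = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd,
                           size=len(ann)))
    truth = ann.copy()
    truth["mu"] = mu
    return ann, truth


def build_sample_sheet(params: SimulationParams,
                       genotypes: Sequence[str] = ("XX", "XY", "XXY", "XO"),
                       ) -> pd.DataFrame:
    """Sample sheet with ``replicates_per_genotype`` lines per genotype.

    Erosion is drawn per line with ``erosion_probability`` for lines carrying
    an inactive X (n_X >= 2); lines with a single X are never eroded.
    """
    params.validate()
    rng = _rng(params, _STREAM_SHEET)
    rows = []
    for g in genotypes:
        if g not in GENOTYPES:
            raise InputError(f"unknown genotype label: {g!r}")
        n_x, _ = GENOTYPES[g]
        for rep in range(1, params.replicates_per_genotype + 1):
            eroded = bool(n_x >= 2 and rng.random() < params.erosion_probability)
            rows.append((f"{g}_{rep}", g, rep, eroded))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "replicate", "eroded"])


def effective_dose(chrom_class: str, x_category: str, trans_beta: float,
                   genotype: GenotypeSpec, params: SimulationParams) -> float:
    """Effective per-gene dose d on the diploid-autosome scale (autosome: 2).

    Closed form over (category, genotype):

    * autosome, non-target: ``2``
    * autosome, trans target: ``2 * 2**(beta * (1 - r))``
    * X xci_subject: ``u`` (one upregulated active copy), or
      ``u * (1 + max(n_X - 1, 0))`` when eroded (full reactivation)
    * X escapee: ``u * (1 + e * max(n_X - 1, 0))``
    * xist_like: ``2`` iff an intact inactive X exists (n_X >= 2, not eroded)
    * Y: ``n_Y``
    """
    u = params.upregulation
    e = params.escape_fraction
    n_inactive = max(genotype.n_x - 1, 0)
    if chrom_class == "autosome":
        if trans_beta != 0.0:
            return 2.0 * 2.0 ** (trans_beta * (1 - genotype.regulator_dose))
        return 2.0
    if chrom_class == "Y":
        return float(genotype.n_y)
    if chrom_class == "X":
        if x_category == "xci_subject":
            return u * (1 + n_inactive) if genotype.eroded else u
        if x_category == "escapee":
            return u * (1.0 + e * n_inactive)
        if x_category == "xist_like":
            return 2.0 if (genotype.n_x >= 2 and not genotype.eroded) else 0.0
    raise InputError(f"unrecognized gene category: ({chrom_class!r}, {x_category!r})")


def _dose_matrix(annotation: pd.DataFrame, specs: Sequence[GenotypeSpec],
                 params: SimulationParams) -> np.ndarray:
    """Genes x specs dose matrix, vectorized over genes."""
    n_genes = len(annotation)
    chrom = annotation["chrom_class"].to_numpy()
    xcat = annotation["x_category"].to_numpy()
    beta = annotation["trans_beta"].to_numpy(dtype=float)
    u, e = params.upregulation, params.escape_fraction

    out = np.empty((n_genes, len(specs)))
    is_aut = chrom == "autosome"
    is_y = chrom == "Y"
    is_xci = xcat == "xci_subject"
    is_esc = xcat == "escapee"
    is_xist = xcat == "xist_like"
    for j, spec in enumerate(specs):
        r = spec.regulator_dose
        n_inact = max(spec.n_x - 1, 0)
        col = np.empty(n_genes)
        col[is_aut] = 2.0 * 2.0 ** (beta[is_aut] * (1 - r))
        col[is_y] = float(spec.n_y)
        col[is_xci] = u * (1 + n_inact) if spec.eroded else u
        col[is_esc] = u * (1.0 + e * n_inact)
        col[is_xist] = 2.0 if (spec.n_x >= 2 and not spec.eroded) else 0.0
        out[:, j] = col
    return out


def true_lfc(truth: pd.DataFrame, genotype_a: str, genotype_b: str) -> pd.Series:
    """True log2 fold change of genotype_b over genotype_a from truth doses.

    Dose-0-vs-positive pairs yield signed infinite sentinels (excluded from
    recovery metrics downstream); 0-vs-0 yields 0.
    """
    da = truth[f"dose_{genotype_a}"].to_numpy(dtype=float)
    db = truth[f"dose_{genotype_b}"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(db) - np.log2(da)
    lfc = np.where((da == 0) & (db == 0), 0.0, lfc)
    return pd.Series(lfc, index=truth.index, name=f"lfc_{genotype_b}_vs_{genotype_a}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean m, var m + alpha m^2) via the gamma-Poisson mixture.

    alpha -> 0 degrades gracefully to Poisson; mean 0 gives count 0 exactly.
    """
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if alpha < 1e-12:
        out[pos] = rng.poisson(mean[pos])
        return out
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean[pos])
    out[pos] = rng.poisson(lam)
    return out


def simulate_counts(annotation: pd.DataFrame, sample_sheet: pd.DataFrame,
                    params: SimulationParams,
                    truth: pd.DataFrame | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the count matrix and fill the truth table.

    Counts are NB with mean ``m_gj = s_j * mu_g * d_gj / 2`` and variance
    ``m + alpha m^2``, drawn independently across genes and samples. The
    returned truth table carries per-gene baseline ``mu`` and the canonical
    (non-eroded) dose per genotype ``dose_XX .. dose_XO``; per-sample doses
    for eroded lines are available through :func:`effective_dose`.

    Returns ``(counts, truth)`` where ``counts`` is a gene x sample
    DataFrame indexed by gene_id.
    """
    params.validate()
    bad = set(sample_sheet["genotype"]) - set(GENOTYPES)
    if bad:
        raise InputError(f"unknown genotype label(s) in sample sheet: {sorted(bad)}")

    if truth is None:
        _, truth = build_annotation(params)
        if not truth["gene_id"].equals(annotation["gene_id"]):
            raise InputError("annotation does not match params-derived gene set; "
                             "pass the truth table from build_annotation")
    truth = truth.copy()

    eroded_col = (sample_sheet["eroded"].astype(bool)
                  if "eroded" in sample_sheet.columns
                  else pd.Series(False, index=sample_sheet.index))
    specs = [GenotypeSpec.from_label(g, eroded=bool(er))
             for g, er in zip(sample_sheet["genotype"], eroded_col)]

    doses = _dose_matrix(annotation, specs, params)

    s = params.library_size_factors
    if s is None:
        s = np.ones(len(sample_sheet))
    s = np.asarray(s, dtype=float)
    if s.shape != (len(sample_sheet),):
        raise ParameterError(
            f"library_size_factors length {s.size} != number of samples "
            f"{len(sample_sheet)}")
    if np.any(s <= 0):
        raise ParameterError("library_size_factors must all be > 0")

    mu = truth["mu"].to_numpy(dtype=float)[:, None]
    mean = s[None, :] * mu * doses / 2.0
    if params.bleed_fraction > 0:
        # cross-mapping background for Y genes in Y-lacking samples
        is_y = (annotation["chrom_class"] == "Y").to_numpy()
        base = s[None, :] * mu * params.bleed_fraction
        mean[is_y] = np.maximum(mean[is_y], np.where(mean[is_y] == 0,
                                                     base[is_y], mean[is_y]))

    rng = _rng(params, _STREAM_COUNTS)
    counts = _nb_draw(rng, mean, params.dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(annotation["gene_id"],
                                                    name="gene_id"),
                             columns=list(sample_sheet["sample_id"]))

    canonical = [GenotypeSpec.from_label(g) for g in GENOTYPES]
    cdoses = _dose_matrix(annotation, canonical, params)
    for j, g in enumerate(GENOTYPES):
        truth[f"dose_{g}"] = cdoses[:, j]
    return counts_df, truth


def simulate_allele_counts(annotation: pd.DataFrame, sample_sheet: pd.DataFrame,
                           params: SimulationParams,
                           coverage_mean: float = 50.0,
                           error_rate: float = 0.01) -> pd.DataFrame:
    """Allele counts at one informative SNP per X-linked gene.

    Total coverage per (gene, sample) ~ Poisson(coverage_mean * d / 2).
    The count from the inactive-X allele (allele B) is Binomial(total, p)
    with p = error_rate for an XCI subject in a non-eroded line and
    p = e / (1 + e) for escapees; erosion reactivates the silent copy fully
    (e = 1, hence p = 0.5) for XCI subjects. Lines with one X are monoallelic
    up to sequencing error.
    """
    params.validate()
    if not 0.0 <= error_rate < 0.5:
        raise ParameterError(f"error_rate must be in [0, 0.5), got {error_rate}")
    if coverage_mean < 0:
        raise ParameterError("coverage_mean must be >= 0")

    rng = _rng(params, _STREAM_ALLELES)
    e = params.escape_fraction
    x_genes = annotation[annotation["chrom_class"] == "X"].reset_index(drop=True)

    eroded_col = (sample_sheet["eroded"].astype(bool)
                  if "eroded" in sample_sheet.columns
                  else pd.Series(False, index=sample_sheet.index))

    records = []
    for (_, samp), eroded in zip(sample_sheet.iterrows(), eroded_col):
        spec = GenotypeSpec.from_label(samp["genotype"], eroded=bool(eroded))
        biallelic_possible = spec.n_x >= 2
        for _, gene in x_genes.iterrows():
            d = effective_dose(gene["chrom_class"], gene["x_category"],
                               gene["trans_beta"], spec, params)
            total = int(rng.poisson(coverage_mean * d / 2.0))
            if gene["x_category"] == "escapee" and biallelic_possible:
                p = e / (1.0 + e)
            elif (gene["x_category"] == "xci_subject" and biallelic_possible
                  and spec.eroded):
                p = 0.5  # e = 1 under erosion
            else:
                p = error_rate
            b = int(rng.binomial(total, p)) if total > 0 else 0
            records.append((gene["gene_id"], f"{gene['gene_id']}_snp1",
                            samp["sample_id"], total - b, b))
    return pd.DataFrame(records, columns=["gene_id", "snp_id", "sample_id",
                                          "count_allele_A", "count_allele_B"])
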