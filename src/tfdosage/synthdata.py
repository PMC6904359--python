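"""Synthetic gene catalogs with known dosage-sensitivity ground truth.

The generator emulates the statistical structure the pipeline assumes: a
~22,810-gene universe containing ~1,639 TFs in 65 families of strongly
skewed sizes; a latent per-gene dosage-sensitivity indicator; four
dosage-evidence sets drawn conditionally independently given the latent
class (Bernoulli(sensitivity) for sensitive genes, Bernoulli(fpr) for
insensitive ones); [0, 1] haploinsufficiency scores from two-component Beta
models; and class-shifted feature distributions (CDS length, dN/dS, PPI
degree, mRNA level, expression-category profiles, binding-site motifs, DBD
counts/sizes, activator/repressor flags).

Default shift magnitudes follow the published contrasts between
dosage-sensitive and dosage-insensitive genes (CDS 2640 vs 1310 bp, dN/dS
0.062 vs 0.257, PPI degree 851 vs 263, motif length 12.0 vs 12.7, etc.);
marginal rates are calibrated so the four evidence sets hold ~6,800 genes
each, their intersection ~850 genes, and ~5.3% of genes exceed pNull 0.9.

Everything is reproducible from the seed: one config, one seed, one byte
stream.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    EXPRESSION_LEVELS,
    EvidenceSets,
    Motif,
    frame_to_records,
    write_gene_set,
    write_gene_table,
    write_gmt,
    write_motifs,
)

EVIDENCE_NAMES = EvidenceSets.EVIDENCE_NAMES

#: TF family sizes: the large named families plus a 46-family long tail,
#: chosen so the pooled small-family categories hold exactly 87 (<=5),
#: 126 (<=7), 186 (<=9) and 238 (<=11) TFs and the total is 1,639 in 65
#: families.
_NAMED_FAMILIES = [
    ("C2H2-ZF", 747),
    ("Homeodomain", 196),
    ("bHLH", 108),
    ("bZIP", 54),
    ("Forkhead", 49),
    ("Nuclear receptor", 46),
    ("HMG/Sox", 30),
    ("ETS", 27),
    ("T-box", 17),
    ("AT-hook", 16),
    ("Homeodomain; POU", 16),
    ("Myb/SANT", 14),
    ("THAP finger", 12),
    ("CENPB", 11),
    ("E2F", 11),
    ("BED ZF", 10),
    ("GATA", 10),
    ("Rel", 10),
    ("Unknown", 69),
]
_TAIL_SIZES = (
    [9, 9, 9, 9, 8, 8, 8]
    + [7, 7, 7, 6, 6, 6]
    + [5] * 5 + [4] * 4 + [3] * 7 + [2] * 8 + [1] * 9
)


def default_family_sizes() -> list[list]:
    sizes = [[name, size] for name, size in _NAMED_FAMILIES]
    sizes += [[f"SmallFam{i + 1:02d}", s] for i, s in enumerate(_TAIL_SIZES)]
    return sizes


assert sum(s for _, s in default_family_sizes()) == 1639
assert len(default_family_sizes()) == 65


@dataclass
class ClassShift:
    """Mean/SD of a feature in the latent-sensitive vs -insensitive class."""

    mean_sensitive: float
    sd_sensitive: float
    mean_insensitive: float
    sd_insensitive: float


@dataclass
class BetaClassPair:
    """Beta(a, b) parameters of a [0,1] score, per latent class."""

    sensitive: list[float]
    insensitive: list[float]


@dataclass
class SimulationConfig:
    """All generator knobs; the defaults are the calibrated study conditions."""

    seed: int = 0
    n_genes: int = 22810
    n_tf: int = 1639
    family_sizes: list[list] = field(default_factory=default_family_sizes)
    n_kzfp: int = 399  # members of C2H2-ZF carrying a KRAB domain

    # latent class and evidence sets
    latent_prevalence: float = 0.35
    set_sensitivity: dict = field(
        default_factory=lambda: {n: 0.57 for n in EVIDENCE_NAMES}
    )
    set_fpr: dict = field(default_factory=lambda: {n: 0.15 for n in EVIDENCE_NAMES})
    #: (family, relative risk): rr multiplies the family's latent prevalence
    #: (capped at 1) and each per-set sensitivity by rr^(1/4) (capped at 1),
    #: so joint four-set membership scales ~linearly with rr.
    planted_families: list[list] = field(
        default_factory=lambda: [["Nuclear receptor", 8.0], ["C2H2-ZF", 0.3]]
    )

    # haploinsufficiency scores
    pli_beta: BetaClassPair = field(
        default_factory=lambda: BetaClassPair([5.0, 1.5], [1.0, 2.2])
    )
    hipred_beta: BetaClassPair = field(
        default_factory=lambda: BetaClassPair([5.0, 1.5], [1.0, 2.2])
    )
    pnull_beta: BetaClassPair = field(
        default_factory=lambda: BetaClassPair([0.3, 3.0], [0.8, 1.0])
    )
    score_missing_rate: float = 0.03
    pnull_cutoff: float = 0.9  # defines the pNull HLOF-tolerant set
    hlof_consang_rate: list[float] = field(default_factory=lambda: [0.01, 0.083])

    # per-gene features (sensitive vs insensitive class)
    cds_length: ClassShift = field(
        default_factory=lambda: ClassShift(2640.0, 1783.0, 1310.0, 1956.0)
    )
    dnds: ClassShift = field(
        default_factory=lambda: ClassShift(0.062, 0.057, 0.257, 0.217)
    )
    ds_shape: float = 4.0
    ds_mean: float = 0.6
    ds_zero_rate: float = 0.02
    ppi_degree_mean: list[float] = field(default_factory=lambda: [851.0, 263.0])
    ppi_dispersion: float = 1.2
    ppi_tf_fraction_mean: list[float] = field(default_factory=lambda: [0.25, 0.17])
    ppi_tf_fraction_conc: float = 20.0
    mrna: ClassShift = field(
        default_factory=lambda: ClassShift(6.36, 0.679, 6.26, 1.767)
    )

    # expression categories over a fixed sample panel
    n_expression_samples: int = 31
    expression_probs: dict = field(
        default_factory=lambda: {
            "sensitive": [0.145, 0.297, 0.190, 0.368],
            "insensitive": [0.100, 0.245, 0.155, 0.500],
        }
    )
    expression_complete_rate: float = 0.8
    expression_partial_rate: float = 0.1

    # TF-only features
    motif_prob: float = 0.7
    motif_length: ClassShift = field(
        default_factory=lambda: ClassShift(12.0, 3.84, 12.7, 4.60)
    )
    motif_base_props: dict = field(
        default_factory=lambda: {
            "sensitive": [0.282, 0.241, 0.243, 0.234],
            "insensitive": [0.301, 0.235, 0.233, 0.231],
        }
    )
    motif_concentration: float = 2.0
    two_dbd_rate: list[float] = field(default_factory=lambda: [0.057, 0.005])
    dbd_size: ClassShift = field(
        default_factory=lambda: ClassShift(118.0, 80.0, 52.0, 30.0)
    )
    activation_rate: list[float] = field(default_factory=lambda: [0.17, 0.008])
    repressor_rate_nonkzfp: list[float] = field(default_factory=lambda: [0.04, 0.03])

    # annotation terms
    n_null_terms: int = 45
    planted_terms: list[list] = field(
        default_factory=lambda: [[f"TERM_PLANTED_{i + 1}", 10.0] for i in range(5)]
    )
    planted_term_rate: float = 0.004
    term_rate_range: list[float] = field(default_factory=lambda: [0.005, 0.02])

    # ---- validation / serialization -------------------------------------
    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_tf <= 0 or self.n_tf > self.n_genes:
            raise ValueError("need 0 < n_tf <= n_genes")
        total = sum(int(s) for _, s in self.family_sizes)
        if total > self.n_tf:
            raise ValueError(f"family sizes sum to {total} > n_tf {self.n_tf}")
        if any(int(s) <= 0 for _, s in self.family_sizes):
            raise ValueError("family sizes must be positive")
        names = [n for n, _ in self.family_sizes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate family names")
        c2h2 = dict((n, int(s)) for n, s in self.family_sizes).get("C2H2-ZF", 0)
        if self.n_kzfp > c2h2:
            raise ValueError("n_kzfp exceeds the C2H2-ZF family size")
        for prob in (
            [self.latent_prevalence, self.score_missing_rate, self.motif_prob,
             self.expression_complete_rate, self.expression_partial_rate,
             self.ds_zero_rate, self.pnull_cutoff]
            + list(self.set_sensitivity.values())
            + list(self.set_fpr.values())
            + list(self.hlof_consang_rate)
            + list(self.activation_rate)
            + list(self.two_dbd_rate)
            + list(self.repressor_rate_nonkzfp)
        ):
            if not (0.0 <= prob <= 1.0):
                raise ValueError(f"probability {prob} outside [0, 1]")
        if set(self.set_sensitivity) != set(EVIDENCE_NAMES) or set(
            self.set_fpr
        ) != set(EVIDENCE_NAMES):
            raise ValueError("set_sensitivity/set_fpr must cover the four sets")
        for fam, rr in self.planted_families:
            if fam not in names:
                raise ValueError(f"planted family {fam!r} not in family_sizes")
            if rr <= 0:
                raise ValueError("planted relative risk must be positive")
        for probs in self.expression_probs.values():
            if len(probs) != 4 or abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError("expression_probs must be 4 values summing to 1")
        for props in self.motif_base_props.values():
            if len(props) != 4 or abs(sum(props) - 1.0) > 1e-3:
                raise ValueError("motif_base_props must be 4 values summing to 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        for name in ("cds_length", "dnds", "mrna", "motif_length", "dbd_size"):
            if name in data and isinstance(data[name], dict):
                data[name] = ClassShift(**data[name])
        for name in ("pli_beta", "hipred_beta", "pnull_beta"):
            if name in data and isinstance(data[name], dict):
                data[name] = BetaClassPair(**data[name])
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "wt", encoding="utf-8") as handle:
                handle.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        elif isinstance(source, str) and "\n" in source:
            data = yaml.safe_load(source)
        else:
            with open(source, "rt", encoding="utf-8") as handle:
                data = yaml.safe_load(handle)
        return cls.from_dict(data)


def default_config(seed: int = 0) -> SimulationConfig:
    """The calibrated default study conditions (see module docstring)."""
    config = SimulationConfig(seed=seed)
    config.validate()
    return config


@dataclass
class GroundTruth:
    """Latent truths the recovery tests check against."""

    latent_sensitive: pd.DataFrame  # columns gene_id, latent_sensitive (0/1)
    planted_families: list[list]
    planted_terms: list[list]

    def sensitive_ids(self) -> set[str]:
        frame = self.latent_sensitive
        return set(frame.loc[frame["latent_sensitive"] == 1, "gene_id"])


@dataclass
class SyntheticData:
    """One generated data set, in memory; ``write`` emits the text files."""

    config: SimulationConfig
    frame: pd.DataFrame
    evidence: EvidenceSets
    motifs: list[Motif]
    terms: dict[str, set[str]]
    truth: GroundTruth
    expression_samples: list[str]

    def write(self, outdir: str) -> dict:
        """Write all artifacts under ``outdir``; returns path map."""
        os.makedirs(outdir, exist_ok=True)
        paths = {"catalog": os.path.join(outdir, "catalog.tsv")}
        write_gene_table(frame_to_records(self.frame), paths["catalog"])
        for name in EvidenceSets.EVIDENCE_NAMES + EvidenceSets.HLOF_NAMES:
            paths[name] = os.path.join(outdir, f"set_{name}.txt")
            write_gene_set(getattr(self.evidence, name), paths[name])
        paths["motifs"] = os.path.join(outdir, "motifs.pfm")
        write_motifs(self.motifs, paths["motifs"])
        paths["gmt"] = os.path.join(outdir, "terms.gmt")
        write_gmt(self.terms, paths["gmt"])
        paths["ground_truth"] = os.path.join(outdir, "ground_truth.tsv")
        self.truth.latent_sensitive.to_csv(
            paths["ground_truth"], sep="\t", index=False
        )
        paths["manifest"] = os.path.join(outdir, "sim_manifest.json")
        manifest = {
            "config": self.config.to_dict(),
            "expression_samples": self.expression_samples,
            "planted_families": self.truth.planted_families,
            "planted_terms": self.truth.planted_terms,
        }
        with open(paths["manifest"], "wt", encoding="utf-8") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")
        return paths


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _select(latent: np.ndarray, sens: np.ndarray, insens: np.ndarray) -> np.ndarray:
    return np.where(latent, sens, insens)


def generate(config: SimulationConfig, with_features: bool = True) -> SyntheticData:
    """Draw one complete synthetic data set from ``config``.

    ``with_features=False`` skips per-gene feature columns, motifs and
    annotation terms (evidence sets, scores and family structure are always
    generated); it is the economical mode for classification/enrichment
    recovery studies that need many replicates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    width = len(str(n))
    gene_ids = np.array([f"G{i + 1:0{width}d}" for i in range(n)])

    # --- TF structure: first n_tf genes are TFs, families in declared order
    is_tf = np.zeros(n, dtype=bool)
    is_tf[: config.n_tf] = True
    tf_family = np.full(n, None, dtype=object)
    pos = 0
    for name, size in config.family_sizes:
        tf_family[pos: pos + int(size)] = name
        pos += int(size)
    if pos < config.n_tf:  # any unassigned TFs fall into the Unknown family
        tf_family[pos: config.n_tf] = "Unknown"
    is_kzfp = np.zeros(n, dtype=bool)
    c2h2_idx = np.flatnonzero(tf_family == "C2H2-ZF")
    is_kzfp[c2h2_idx[: config.n_kzfp]] = True

    # --- latent dosage sensitivity, with planted family relative risks
    prevalence = np.full(n, config.latent_prevalence)
    sens_mult = np.ones(n)
    for fam, rr in config.planted_families:
        members = tf_family == fam
        prevalence[members] = min(1.0, float(rr) * config.latent_prevalence)
        sens_mult[members] = float(rr) ** 0.25
    latent = rng.random(n) < prevalence

    # --- four evidence sets, conditionally independent given the class
    evidence_members: dict[str, set[str]] = {}
    for name in EVIDENCE_NAMES:
        p_hit = np.where(
            latent,
            np.minimum(1.0, config.set_sensitivity[name] * sens_mult),
            config.set_fpr[name],
        )
        members = rng.random(n) < p_hit
        evidence_members[name] = set(gene_ids[members])

    # --- haploinsufficiency scores
    def draw_scores(pair: BetaClassPair) -> np.ndarray:
        a_s, b_s = pair.sensitive
        a_i, b_i = pair.insensitive
        return _select(latent, rng.beta(a_s, b_s, n), rng.beta(a_i, b_i, n))

    pli = draw_scores(config.pli_beta)
    hipred = draw_scores(config.hipred_beta)
    pnull = draw_scores(config.pnull_beta)
    score_missing = rng.random(n) < config.score_missing_rate

    hlof_pnull = set(gene_ids[(pnull > config.pnull_cutoff) & ~score_missing])
    r_s, r_i = config.hlof_consang_rate
    hlof_consang = set(gene_ids[rng.random(n) < np.where(latent, r_s, r_i)])

    evidence = EvidenceSets(
        universe=set(gene_ids),
        hlof_pnull=hlof_pnull,
        hlof_consang=hlof_consang,
        **evidence_members,
    )

    frame = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": [f"SYM{i + 1}" for i in range(n)],
            "is_tf": is_tf,
            "tf_family": tf_family,
            "is_kzfp": is_kzfp,
        }
    )
    for col in (
        "cds_length", "dn", "ds", "pli", "hipred", "pnull", "ppi_degree",
        "ppi_tf_fraction", "mrna_level", "expression_levels", "dbd_sizes",
    ):
        frame[col] = None
    frame["has_activation_domain"] = False
    frame["has_repressor_domain"] = False

    frame["pli"] = np.where(score_missing, None, np.round(pli, 6))
    frame["hipred"] = np.where(score_missing, None, np.round(hipred, 6))
    frame["pnull"] = np.where(score_missing, None, np.round(pnull, 6))

    samples = [f"S{i + 1:02d}" for i in range(config.n_expression_samples)]
    motif_list: list[Motif] = []
    terms: dict[str, set[str]] = {}

    if with_features:
        # CDS length: lognormal, rounded to a positive multiple of 3
        mu_s, sg_s = _lognormal_params(
            config.cds_length.mean_sensitive, config.cds_length.sd_sensitive
        )
        mu_i, sg_i = _lognormal_params(
            config.cds_length.mean_insensitive, config.cds_length.sd_insensitive
        )
        cds = _select(
            latent, rng.lognormal(mu_s, sg_s, n), rng.lognormal(mu_i, sg_i, n)
        )
        cds = np.maximum(1, np.round(cds / 3.0)).astype(int) * 3
        frame["cds_length"] = cds

        # dS then dN = (dN/dS) * dS; a small fraction of genes has dS = 0
        ds = rng.gamma(config.ds_shape, config.ds_mean / config.ds_shape, n)
        ds_zero = rng.random(n) < config.ds_zero_rate
        ds[ds_zero] = 0.0

        def gamma_from(mean, sd, size):
            shape = (mean / sd) ** 2
            return rng.gamma(shape, mean / shape, size)

        ratio = _select(
            latent,
            gamma_from(config.dnds.mean_sensitive, config.dnds.sd_sensitive, n),
            gamma_from(config.dnds.mean_insensitive, config.dnds.sd_insensitive, n),
        )
        frame["ds"] = np.round(ds, 4)
        frame["dn"] = np.round(ratio * ds, 4)

        # PPI degree (negative binomial) and TF fraction of interactors
        r = config.ppi_dispersion

        def negbin(mean):
            return rng.negative_binomial(r, r / (r + mean), n)

        frame["ppi_degree"] = _select(
            latent,
            negbin(config.ppi_degree_mean[0]),
            negbin(config.ppi_degree_mean[1]),
        ).astype(int)

        def beta_mean(mean, conc):
            return rng.beta(mean * conc, (1 - mean) * conc, n)

        frame["ppi_tf_fraction"] = np.round(
            _select(
                latent,
                beta_mean(config.ppi_tf_fraction_mean[0], config.ppi_tf_fraction_conc),
                beta_mean(config.ppi_tf_fraction_mean[1], config.ppi_tf_fraction_conc),
            ),
            4,
        )

        frame["mrna_level"] = np.round(
            _select(
                latent,
                rng.normal(config.mrna.mean_sensitive, config.mrna.sd_sensitive, n),
                rng.normal(config.mrna.mean_insensitive, config.mrna.sd_insensitive, n),
            ),
            4,
        )

        # protein expression categories over the fixed sample panel
        profile_draw = rng.random(n)
        complete = profile_draw < config.expression_complete_rate
        partial = (~complete) & (
            profile_draw < config.expression_complete_rate + config.expression_partial_rate
        )
        p_sens = np.array(config.expression_probs["sensitive"])
        p_ins = np.array(config.expression_probs["insensitive"])
        n_samples = config.n_expression_samples
        level_draws = rng.random((n, n_samples))
        cum_s = np.cumsum(p_sens)
        cum_i = np.cumsum(p_ins)
        idx_s = np.searchsorted(cum_s, level_draws, side="right")
        idx_i = np.searchsorted(cum_i, level_draws, side="right")
        level_idx = np.where(latent[:, None], idx_s, idx_i).clip(0, 3)
        n_present = rng.integers(1, n_samples, n)  # for partial profiles
        expression = np.full(n, None, dtype=object)
        for i in range(n):
            if complete[i]:
                keep = range(n_samples)
            elif partial[i]:
                keep = range(int(n_present[i]))
            else:
                continue
            expression[i] = {
                samples[j]: EXPRESSION_LEVELS[level_idx[i, j]] for j in keep
            }
        frame["expression_levels"] = expression

        # DBDs, activation/repressor annotations (TFs only)
        two_dbd = rng.random(n) < _select(
            latent, np.full(n, config.two_dbd_rate[0]), np.full(n, config.two_dbd_rate[1])
        )
        mu_ds, sg_ds = _lognormal_params(
            config.dbd_size.mean_sensitive, config.dbd_size.sd_sensitive
        )
        mu_di, sg_di = _lognormal_params(
            config.dbd_size.mean_insensitive, config.dbd_size.sd_insensitive
        )
        size_draws = _select(
            latent[:, None].repeat(2, axis=1),
            rng.lognormal(mu_ds, sg_ds, (n, 2)),
            rng.lognormal(mu_di, sg_di, (n, 2)),
        )
        size_draws = np.maximum(10, np.round(size_draws)).astype(int)
        dbd = np.full(n, None, dtype=object)
        for i in range(config.n_tf):
            k = 2 if two_dbd[i] else 1
            dbd[i] = [int(v) for v in size_draws[i, :k]]
        frame["dbd_sizes"] = dbd

        act = rng.random(n) < _select(
            latent,
            np.full(n, config.activation_rate[0]),
            np.full(n, config.activation_rate[1]),
        )
        rep = rng.random(n) < _select(
            latent,
            np.full(n, config.repressor_rate_nonkzfp[0]),
            np.full(n, config.repressor_rate_nonkzfp[1]),
        )
        frame["has_activation_domain"] = act & is_tf & ~is_kzfp
        frame["has_repressor_domain"] = (rep & is_tf) | is_kzfp

        # binding-site motifs: Dirichlet position columns, class-shifted
        has_motif = (rng.random(n) < config.motif_prob) & is_tf
        lengths = np.clip(
            np.round(
                _select(
                    latent,
                    rng.normal(
                        config.motif_length.mean_sensitive,
                        config.motif_length.sd_sensitive,
                        n,
                    ),
                    rng.normal(
                        config.motif_length.mean_insensitive,
                        config.motif_length.sd_insensitive,
                        n,
                    ),
                )
            ),
            5, 30,
        ).astype(int)
        alpha_s = np.array(config.motif_base_props["sensitive"]) * config.motif_concentration * 4
        alpha_i = np.array(config.motif_base_props["insensitive"]) * config.motif_concentration * 4
        for i in np.flatnonzero(has_motif):
            alpha = alpha_s if latent[i] else alpha_i
            gamma = rng.gamma(alpha, 1.0, (lengths[i], 4))
            matrix = gamma / gamma.sum(axis=1, keepdims=True)
            motif_list.append(Motif(tf_gene_id=str(gene_ids[i]), matrix=matrix))

        # annotation terms: null terms plus terms planted among sensitive genes
        lo, hi = config.term_rate_range
        for t in range(config.n_null_terms):
            rate = rng.uniform(lo, hi)
            members = rng.random(n) < rate
            terms[f"TERM_NULL_{t + 1}"] = set(gene_ids[members])
        for term_name, fold in config.planted_terms:
            rate = config.planted_term_rate
            p_member = np.where(latent, min(1.0, float(fold) * rate), rate)
            members = rng.random(n) < p_member
            terms[str(term_name)] = set(gene_ids[members])

    truth = GroundTruth(
        latent_sensitive=pd.DataFrame(
            {"gene_id": gene_ids, "latent_sensitive": latent.astype(int)}
        ),
        planted_families=[list(x) for x in config.planted_families],
        planted_terms=[list(x) for x in config.planted_terms],
    )
    return SyntheticData(
        config=config,
        frame=frame,
        evidence=evidence,
        motifs=motif_list,
        terms=terms,
        truth=truth,
        expression_samples=samples,
    )
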