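"""Synthetic maternal-serum lipidomics cohorts with known ground truth.

The generator emulates the data structure of a 64-sample severe
preeclampsia case/control serum lipidomics study: ~729 lipid species over
~15 classes, log-normal abundances with block-correlation (module)
structure, an oxidized-phospholipid block whose within-condition
correlation is rewired between case and control, planted case/control
abundance effects on a known lipid subset, clinical confounders drawn from
the published cohort summary (gestational age lower in cases; gestational
diabetes and smoking present only in cases), left-censored missingness,
and a planted lipid -> lipid -> outcome causal chain along the
gestational-age ordering.

Every stage draws from its own substream of a single seed
(``default_rng([seed, stage])``), so any stage is reproducible in
isolation and identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .containers import LipidMatrix, write_lipid_matrix, write_clinical, write_json

# rng substream ids, one per generation stage
_SUB_COVARIATES = 1
_SUB_ABUNDANCE = 2
_SUB_CHAIN = 3
_SUB_MISSING = 4


@dataclass
class ModuleSpec:
    """One correlated lipid block.

    ``cor_case``/``cor_ctrl`` are the common within-block correlations of
    log abundances in each condition; they differ for a rewired block.
    """
    size: int
    cor_case: float
    cor_ctrl: float
    lipid_class: str | None = None  # bias block members toward this class


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    Defaults reproduce the reference study conditions: 44 cases vs 20
    controls, 729 lipid species, a large TAG-like block, a rewired
    oxidized-phospholipid block (case correlation 0.8, control 0.3), ten
    planted effect lipids at |log2 fold change| 1, confounders drawn from
    the published Table-1 summary, and a two-lipid causal chain into the
    outcome.
    """
    n_case: int = 44
    n_ctrl: int = 20
    n_lipids: int = 729
    class_proportions: dict = field(
        default_factory=lambda: dict(datasets.LIPID_CLASS_PROPORTIONS))
    modules: list = field(default_factory=lambda: [
        ModuleSpec(60, 0.6, 0.6, "TAG"),
        ModuleSpec(30, 0.8, 0.3, "OxPC"),   # rewired oxidized-PL block
        ModuleSpec(20, 0.7, 0.7, "PC"),
    ])
    #: (lipid index, log2 fold change in cases); defaults place ten
    #: down-regulated species outside the module blocks, mirroring the
    #: predominance of down-regulated markers in serum.
    effect_lipids: list = field(default_factory=lambda:
                                [(i, -1.0) for i in range(110, 120)])
    confounder_continuous: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in datasets.CONTINUOUS.items()})
    confounder_categorical: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in datasets.CATEGORICAL.items()})
    missing_rate: float = 0.10
    censoring_steepness: float = 2.0
    #: lipid indices forming a lag-1 chain ending at the outcome.
    causal_chain: list = field(default_factory=lambda: [120, 121])
    #: lag-1 coefficients, one per chain edge (last one is lipid->outcome).
    causal_coefficients: list = field(default_factory=lambda: [0.8, 1.0])
    baseline_log2_mean: tuple = (8.0, 16.0)   # per-lipid uniform range
    log2_sd: float = 1.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_ctrl

    def validate(self) -> None:
        if sum(m.size for m in self.modules) > self.n_lipids:
            raise ValueError("module sizes sum exceeds n_lipids")
        for name, spec in (("missing_rate", self.missing_rate),):
            if not 0 <= spec < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for i, m in enumerate(self.modules):
            for cond, r in (("case", m.cor_case), ("control", m.cor_ctrl)):
                # exchangeable blocks with r in [0,1] are always PSD; anything
                # outside that range would make the block correlation invalid
                if not (0.0 <= r <= 1.0):
                    raise ValueError(
                        f"module {i} requests a non-positive-semidefinite "
                        f"{cond} correlation {r} for size {m.size}")
        if len(self.causal_coefficients) != len(self.causal_chain):
            raise ValueError("need one causal coefficient per chain edge")

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        d["modules"] = [asdict(m) for m in self.modules]
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["modules"] = [ModuleSpec(**m) for m in d.get("modules", [])]
        d["effect_lipids"] = [tuple(e) for e in d.get("effect_lipids", [])]
        d["baseline_log2_mean"] = tuple(d.get("baseline_log2_mean", (8.0, 16.0)))
        for key in ("confounder_continuous", "confounder_categorical"):
            if key in d:
                d[key] = {var: {g: tuple(v) for g, v in groups.items()}
                          for var, groups in d[key].items()}
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth planted in a synthetic cohort."""
    true_differential: list          # lipid ids with planted status effects
    true_modules: dict               # lipid id -> module id or "background"
    rewired_module: str | None       # module whose correlation differs by condition
    true_causal_edges: list          # directed (from, to) pairs, outcome = "status"

    def to_json(self, path: str | Path) -> Path:
        return write_json(asdict(self), path)


def _lipid_names(config: SimConfig, rng: np.random.Generator) -> tuple[list, pd.Series]:
    """Assign class labels (module blocks biased to their stated class) and
    synthesize species names like ``PC 34:2`` / ``OxPE 38:4``."""
    props = pd.Series(config.class_proportions, dtype=float)
    props = props / props.sum()
    classes = np.array(rng.choice(props.index, size=config.n_lipids, p=props.values))
    pos = 0
    for m in config.modules:
        if m.lipid_class is not None:
            classes[pos:pos + m.size] = m.lipid_class
        pos += m.size
    carbons = rng.integers(14, 60, size=config.n_lipids)
    dbs = rng.integers(0, 7, size=config.n_lipids)
    names, seen = [], set()
    for i, (cls, c, d) in enumerate(zip(classes, carbons, dbs)):
        name = f"{cls} {c}:{d}"
        while name in seen:
            c += 1
            name = f"{cls} {c}:{d}"
        seen.add(name)
        names.append(name)
    return names, pd.Series(classes, index=names, name="lipid_class")


def _draw_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_samples
    status = np.array([1] * config.n_case + [0] * config.n_ctrl)
    rows = {"status": status}
    for var, groups in config.confounder_continuous.items():
        vals = np.empty(n)
        for g, idx in (("case", status == 1), ("control", status == 0)):
            mean, sd = groups[g]
            vals[idx] = rng.normal(mean, sd, size=idx.sum())
        rows[var] = np.round(vals, 3)
    for var, levels in config.confounder_categorical.items():
        names = list(levels)
        counts = np.array([levels[k] for k in names], dtype=float)  # (level, [ctrl, case])
        vals = np.empty(n, dtype=object)
        for gi, idx in ((1, status == 1), (0, status == 0)):
            p = counts[:, gi]
            p = p / p.sum()
            vals[idx] = rng.choice(names, size=idx.sum(), p=p)
        rows[var] = vals
    sample_ids = [f"case_{i:02d}" for i in range(config.n_case)] + \
                 [f"ctrl_{i:02d}" for i in range(config.n_ctrl)]
    clinical = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample"))
    # gestational age must be positive and is the pseudo-time axis
    clinical["gestational_age"] = clinical["gestational_age"].clip(lower=24.0)
    return clinical


def _block_correlated(rng: np.random.Generator, n: int, size: int, r: float) -> np.ndarray:
    """n draws of an exchangeable-correlation-(r) standard normal block."""
    common = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, size))
    return np.sqrt(r) * common + np.sqrt(1 - r) * noise


def simulate_cohort(config: SimConfig) -> tuple[LipidMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate one complete cohort (no missingness applied).

    Returns the raw-scale lipid matrix, the clinical table, and the
    planted ground truth.  Apply :func:`inject_missingness` afterwards to
    emulate left-censored missing values.
    """
    config.validate()
    rng_cov = np.random.default_rng([config.seed, _SUB_COVARIATES])
    rng_ab = np.random.default_rng([config.seed, _SUB_ABUNDANCE])
    rng_ch = np.random.default_rng([config.seed, _SUB_CHAIN])

    clinical = _draw_covariates(config, rng_cov)
    status = clinical["status"].to_numpy()
    n = config.n_samples

    names, classes = _lipid_names(config, rng_ab)

    # log2-scale abundances: block-correlated within modules, iid outside
    z = np.empty((n, config.n_lipids))
    module_of = {}
    pos = 0
    case_idx = status == 1
    for mi, m in enumerate(config.modules):
        label = f"module_{mi}"
        block = np.empty((n, m.size))
        block[case_idx] = _block_correlated(rng_ab, int(case_idx.sum()), m.size, m.cor_case)
        block[~case_idx] = _block_correlated(rng_ab, int((~case_idx).sum()), m.size, m.cor_ctrl)
        z[:, pos:pos + m.size] = block
        for j in range(pos, pos + m.size):
            module_of[names[j]] = label
        pos += m.size
    z[:, pos:] = rng_ab.standard_normal((n, config.n_lipids - pos))
    for j in range(pos, config.n_lipids):
        module_of[names[j]] = "background"

    # planted case/control effects (log2 units)
    for idx, lfc in config.effect_lipids:
        z[case_idx, idx] += lfc

    # causal chain along the gestational-age pseudo-time ordering
    order = np.argsort(clinical["gestational_age"].to_numpy(), kind="stable")
    y_ord = status[order].astype(float)
    chain = list(config.causal_chain)
    coefs = list(config.causal_coefficients)
    if chain:
        series = np.zeros((len(chain), n))
        # root lipid: AR(1) along pseudo-time, independent of the outcome
        e = rng_ch.standard_normal(n)
        series[0, 0] = e[0]
        for t in range(1, n):
            series[0, t] = 0.5 * series[0, t - 1] + np.sqrt(1 - 0.25) * e[t]
        # downstream lipids: driven by the predecessor's lag-1 value; the
        # last chain lipid additionally anticipates the next sample's
        # outcome, which is how a fixed 0/1 label can be given a
        # recoverable lipid->outcome edge
        for j in range(1, len(chain)):
            e = rng_ch.standard_normal(n)
            series[j, 0] = e[0]
            for t in range(1, n):
                series[j, t] = coefs[j - 1] * series[j - 1, t - 1] + 0.6 * e[t]
        gamma = coefs[-1]
        last = len(chain) - 1
        series[last, :-1] += gamma * (y_ord[1:] - y_ord[1:].mean())
        for j, idx in enumerate(chain):
            z[order, idx] = series[j] / series[j].std()

    # per-lipid baseline means, then back to the raw abundance scale
    lo, hi = config.baseline_log2_mean
    mu = rng_ab.uniform(lo, hi, size=config.n_lipids)
    values = np.power(2.0, mu + config.log2_sd * z)
    matrix = LipidMatrix(
        values=pd.DataFrame(values, index=clinical.index, columns=names),
        lipid_classes=classes, scale_state="raw")

    rewired = None
    for mi, m in enumerate(config.modules):
        if m.cor_case != m.cor_ctrl:
            rewired = f"module_{mi}"
            break
    chain_names = [names[i] for i in chain]
    edges = [(chain_names[j], chain_names[j + 1]) for j in range(len(chain) - 1)]
    if chain_names:
        edges.append((chain_names[-1], "status"))
    truth = SyntheticTruth(
        true_differential=[names[i] for i, _ in config.effect_lipids],
        true_modules=module_of,
        rewired_module=rewired,
        true_causal_edges=edges,
    )
    return matrix, clinical, truth


def inject_missingness(matrix: LipidMatrix, missing_rate: float,
                       censoring_steepness: float = 2.0,
                       seed: int = 0) -> LipidMatrix:
    """Left-censor the matrix: low-abundance cells go missing more often.

    The per-cell missingness probability is a logistic function of the
    per-lipid z-scored log2 abundance, ``sigmoid(c - steepness * z)``, with
    the intercept ``c`` calibrated so the expected missing fraction equals
    ``missing_rate``.  MNAR behaviour typical of quantification limits in
    MS lipidomics.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    if matrix.values.isna().any().any():
        raise ValueError("matrix already contains missing values")
    if missing_rate == 0:
        return matrix
    rng = np.random.default_rng([seed, _SUB_MISSING])
    logv = np.log2(matrix.values.to_numpy())
    zs = (logv - logv.mean(axis=0)) / logv.std(axis=0, ddof=0)
    from scipy.special import expit
    lo, hi = -30.0, 30.0
    for _ in range(80):   # bisection for the calibrating intercept
        c = 0.5 * (lo + hi)
        if expit(c - censoring_steepness * zs).mean() < missing_rate:
            lo = c
        else:
            hi = c
    p = expit(c - censoring_steepness * zs)
    mask = rng.random(zs.shape) < p
    values = matrix.values.where(~mask)
    return LipidMatrix(values=values, lipid_classes=matrix.lipid_classes,
                       missing_mask=pd.DataFrame(mask, index=matrix.values.index,
                                                 columns=matrix.values.columns),
                       scale_state=matrix.scale_state)


def write_cohort(matrix: LipidMatrix, clinical: pd.DataFrame, truth: SyntheticTruth,
                 config: SimConfig, outdir: str | Path) -> dict:
    """Write the full cohort as TSV/JSON/YAML artifacts under ``outdir``."""
    outdir = Path(outdir)
    paths = write_lipid_matrix(matrix, outdir / "cohort")
    paths["clinical"] = write_clinical(clinical, outdir / "clinical.tsv")
    paths["truth"] = truth.to_json(outdir / "truth.json")
    paths["config"] = config.to_yaml(outdir / "sim_config.yaml")
    return paths
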