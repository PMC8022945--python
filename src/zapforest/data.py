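"""Synthetic genotype/phenotype data with hurdle-count structure, plus
reading/writing of the delimited real-data formats.

A dataset couples a binary (0/1 coded) marker matrix over lines with a long
phenotype table of (line, environment, count) records — the same lines
replicated across environments.  The simulator drives the zero probability
``theta`` through a logit link and the truncated-Poisson rate ``mu`` through
a log link, each a sparse linear function of markers plus per-environment
offsets, and draws counts from the hurdle sampler, returning the true
per-record parameters for recovery tests.
"""

from __future__ import annotations

import dataclasses
import math
import subprocess
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import zap_sample

__all__ = [
    "GenomicDataset",
    "EffectConfig",
    "simulate_markers",
    "simulate_zap_phenotypes",
    "build_design",
    "read_dataset",
    "write_dataset",
    "phenotype_summary",
    "zero_percentage",
    "dataset1_like",
    "dataset2_like",
    "rdata_to_csvs",
]

_THETA_CLIP = 1e-6


@dataclasses.dataclass
class GenomicDataset:
    """Lines x environments phenotype records joined to a 0/1 marker matrix."""

    lines: list
    environments: list
    markers: pd.DataFrame  # index: line, columns: marker names, values in {0,1}
    records: pd.DataFrame  # columns: line, environment, count

    def __post_init__(self) -> None:
        vals = self.markers.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("marker entries must be coded 0 (absence) or 1 (presence)")
        counts = self.records["count"].to_numpy()
        if np.any(counts < 0) or np.any(counts != np.floor(counts)):
            raise ValueError("counts must be nonnegative integers")
        unknown = set(self.records["line"]) - set(self.lines)
        if unknown:
            raise ValueError(f"records reference unknown lines: {sorted(unknown)[:5]}")
        unknown_env = set(self.records["environment"]) - set(self.environments)
        if unknown_env:
            raise ValueError(f"records reference unknown environments: {sorted(unknown_env)}")

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    @property
    def counts(self) -> np.ndarray:
        return self.records["count"].to_numpy(dtype=np.int64)


@dataclasses.dataclass(frozen=True)
class EffectConfig:
    """Sparse linear effect architecture on the two link scales."""

    n_informative_theta: int = 10
    n_informative_mu: int = 10
    effect_size_theta: float = 1.0
    effect_size_mu: float = 0.3
    intercept_theta: float = 0.0  # logit scale
    intercept_mu: float = 0.7  # log scale
    env_effects_theta: Optional[Sequence[float]] = None
    env_effects_mu: Optional[Sequence[float]] = None
    target_zero_fraction: Optional[float] = None  # recalibrates the theta intercept
    seed: int = 0


def simulate_markers(n_lines: int, p: int, maf_range=(0.1, 0.5), seed: int = 0) -> pd.DataFrame:
    """Binary marker matrix; column j is Bernoulli(maf_j), maf_j ~ U(maf_range)."""
    lo, hi = maf_range
    if not 0.0 < lo <= hi < 1.0:
        raise ValueError("need 0 < maf_low <= maf_high < 1")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=p)
    geno = (rng.random((n_lines, p)) < mafs).astype(np.int8)
    return pd.DataFrame(
        geno,
        index=[f"G{i + 1}" for i in range(n_lines)],
        columns=[f"V{j + 1}" for j in range(p)],
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(linpred: np.ndarray, target: float) -> float:
    """Shift so mean(sigmoid(linpred + shift)) == target, by bisection."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if _sigmoid(linpred + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_zap_phenotypes(
    markers: pd.DataFrame,
    environments: Sequence[str],
    effects: EffectConfig,
) -> tuple[GenomicDataset, pd.DataFrame]:
    """Draw hurdle-Poisson counts for every line in every environment.

    Returns the dataset and a truth table with per-record ``theta`` and
    ``mu`` (for parameter-recovery tests).  Under the hurdle construction a
    record is zero exactly when its structural-zero coin lands, so the
    population zero fraction equals the mean of ``theta``.
    """
    p = markers.shape[1]
    if effects.n_informative_theta > p or effects.n_informative_mu > p:
        raise ValueError("informative marker counts exceed p")
    rng = np.random.default_rng(effects.seed)
    lines = list(markers.index)
    environments = list(environments)
    geno = markers.to_numpy(dtype=float)

    beta_theta = np.zeros(p)
    idx_theta = rng.choice(p, size=effects.n_informative_theta, replace=False)
    beta_theta[idx_theta] = effects.effect_size_theta * rng.choice([-1.0, 1.0], idx_theta.size)
    beta_mu = np.zeros(p)
    idx_mu = rng.choice(p, size=effects.n_informative_mu, replace=False)
    beta_mu[idx_mu] = effects.effect_size_mu * rng.choice([-1.0, 1.0], idx_mu.size)

    n_env = len(environments)
    env_t = np.asarray(
        effects.env_effects_theta if effects.env_effects_theta is not None else np.zeros(n_env),
        dtype=float,
    )
    env_m = np.asarray(
        effects.env_effects_mu if effects.env_effects_mu is not None else np.zeros(n_env),
        dtype=float,
    )
    if env_t.size != n_env or env_m.size != n_env:
        raise ValueError("environment effect vectors must match the number of environments")

    rows = []
    lin_theta = []
    lin_mu = []
    for ei, env in enumerate(environments):
        lt = effects.intercept_theta + geno @ beta_theta + env_t[ei]
        lm = effects.intercept_mu + geno @ beta_mu + env_m[ei]
        lin_theta.append(lt)
        lin_mu.append(lm)
        rows.extend((line, env) for line in lines)
    lin_theta = np.concatenate(lin_theta)
    lin_mu = np.concatenate(lin_mu)
    if effects.target_zero_fraction is not None:
        lin_theta += _calibrate_intercept(lin_theta, effects.target_zero_fraction)
    theta = np.clip(_sigmoid(lin_theta), _THETA_CLIP, 1.0 - _THETA_CLIP)
    mu = np.exp(np.clip(lin_mu, -30.0, 30.0))
    counts = zap_sample(theta, mu, seed=rng.integers(2**63))

    records = pd.DataFrame(
        {
            "line": [r[0] for r in rows],
            "environment": [r[1] for r in rows],
            "count": counts,
        }
    )
    truth = records[["line", "environment"]].copy()
    truth["theta"] = theta
    truth["mu"] = mu
    dataset = GenomicDataset(
        lines=lines, environments=environments, markers=markers, records=records
    )
    return dataset, truth


def build_design(
    dataset: GenomicDataset, include_GE: bool = False, ge_mode: str = "indicator"
) -> tuple[np.ndarray, list]:
    """Design matrix for the records: environment dummies, then marker
    columns replicated to records by line, then (optionally) GE columns.

    ``ge_mode='indicator'`` emits one line-within-environment indicator per
    (line, environment) pair, labeled ``Z.{line}.{env}``; ``'product'``
    emits marker x environment-dummy products instead.
    """
    rec = dataset.records
    if rec.duplicated(["line", "environment"]).any():
        raise ValueError("duplicate (line, environment) records")
    env_labels = list(dataset.environments)
    env_idx = rec["environment"].map({e: i for i, e in enumerate(env_labels)}).to_numpy()
    n = len(rec)
    env_block = np.zeros((n, len(env_labels)))
    env_block[np.arange(n), env_idx] = 1.0
    marker_block = dataset.markers.loc[rec["line"]].to_numpy(dtype=float)
    blocks = [env_block, marker_block]
    labels = env_labels + list(dataset.markers.columns)
    if include_GE:
        if ge_mode == "indicator":
            pairs = [(line, env) for line in dataset.lines for env in env_labels]
            pair_pos = {pe: k for k, pe in enumerate(pairs)}
            ge = np.zeros((n, len(pairs)))
            for i, (line, env) in enumerate(zip(rec["line"], rec["environment"])):
                ge[i, pair_pos[(line, env)]] = 1.0
            blocks.append(ge)
            labels += [f"Z.{line}.{env}" for line, env in pairs]
        elif ge_mode == "product":
            prods = []
            for ei, env in enumerate(env_labels):
                prods.append(marker_block * env_block[:, [ei]])
                labels += [f"{m}.{env}" for m in dataset.markers.columns]
            blocks.extend(prods)
        else:
            raise ValueError(f"unknown ge_mode: {ge_mode!r}")
    return np.concatenate(blocks, axis=1), labels


# ---------------------------------------------------------------------------
# presets mirroring the two real datasets' shapes


def dataset1_like(
    p: int = 1635, seed: int = 0, n_lines: int = 115, zero_fraction: float = 0.35
) -> tuple[GenomicDataset, pd.DataFrame]:
    """115 lines x 3 environments, binary markers, ~35% zeros."""
    markers = simulate_markers(n_lines, p, seed=seed)
    effects = EffectConfig(
        n_informative_theta=min(10, p),
        n_informative_mu=min(10, p),
        effect_size_theta=1.2,
        effect_size_mu=0.25,
        intercept_mu=0.6,
        env_effects_theta=[0.0, -0.4, 0.4],
        env_effects_mu=[0.0, 0.2, -0.2],
        target_zero_fraction=zero_fraction,
        seed=seed + 1,
    )
    return simulate_zap_phenotypes(markers, ["Env1", "Env2", "Env3"], effects)


def dataset2_like(
    p: int = 11617, seed: int = 0, n_lines: int = 438, zero_fraction: float = 0.06
) -> tuple[GenomicDataset, pd.DataFrame]:
    """438 lines x 6 environments, binary markers, few zeros."""
    markers = simulate_markers(n_lines, p, seed=seed)
    effects = EffectConfig(
        n_informative_theta=min(15, p),
        n_informative_mu=min(15, p),
        effect_size_theta=1.0,
        effect_size_mu=0.2,
        intercept_mu=1.6,
        env_effects_theta=[0.0, 0.2, -0.2, 0.1, -0.1, 0.0],
        env_effects_mu=[0.0, 0.1, -0.1, 0.05, -0.05, 0.0],
        target_zero_fraction=zero_fraction,
        seed=seed + 1,
    )
    return simulate_zap_phenotypes(markers, [f"Env{i}" for i in range(1, 7)], effects)


# ---------------------------------------------------------------------------
# delimited-text IO


def write_dataset(dataset: GenomicDataset, directory) -> tuple[Path, Path]:
    """Write ``phenotype.csv`` (long) and ``genotype.csv`` (wide) to a dir."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pheno_path = directory / "phenotype.csv"
    geno_path = directory / "genotype.csv"
    dataset.records.to_csv(pheno_path, index=False)
    dataset.markers.rename_axis("line").to_csv(geno_path)
    return pheno_path, geno_path


def read_dataset(phenotype_path, genotype_path, trait: str = "count") -> GenomicDataset:
    """Read a phenotype CSV (line, environment, <trait>) and a wide 0/1
    genotype CSV (first column = line).  Round-trips :func:`write_dataset`.
    """
    pheno = pd.read_csv(phenotype_path)
    geno = pd.read_csv(genotype_path, index_col=0)
    for col in ("line", "environment"):
        if col not in pheno.columns:
            raise ValueError(f"phenotype file missing column {col!r}")
    if trait not in pheno.columns:
        raise ValueError(f"phenotype file has no trait column {trait!r}")
    records = pheno[["line", "environment", trait]].rename(columns={trait: "count"})
    counts = records["count"].to_numpy()
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be nonnegative integers")
    records["count"] = counts.astype(np.int64)
    env_order = list(dict.fromkeys(records["environment"]))
    return GenomicDataset(
        lines=list(geno.index.astype(str)),
        environments=env_order,
        markers=geno,
        records=records.assign(line=records["line"].astype(str)),
    )


def zero_percentage(counts) -> float:
    """Share of zero records, in percent."""
    counts = np.asarray(counts)
    return 100.0 * float(np.mean(counts == 0))


def phenotype_summary(counts) -> dict:
    """Six-number summary (min / quartiles / mean / max) of pooled counts."""
    counts = np.asarray(counts, dtype=float)
    q1, med, q3 = np.quantile(counts, [0.25, 0.5, 0.75])
    return {
        "min": float(counts.min()),
        "q1": float(q1),
        "median": float(med),
        "mean": float(counts.mean()),
        "q3": float(q3),
        "max": float(counts.max()),
        "zero_pct": zero_percentage(counts),
        "n": int(counts.size),
    }


def rdata_to_csvs(rdata_path, out_dir) -> list:
    """Dump every object in an .RData file to CSV via Rscript.

    The deposited files are R serializations; this converter needs a working
    ``Rscript`` on PATH and writes one ``<object>.csv`` per stored data frame
    or matrix, which can then be assembled into the phenotype/genotype CSVs
    that :func:`read_dataset` expects.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    script = (
        f'load("{Path(rdata_path).as_posix()}"); '
        "for (nm in ls()) { obj <- get(nm); "
        "if (is.data.frame(obj) || is.matrix(obj)) "
        f'write.csv(as.data.frame(obj), file.path("{out_dir.as_posix()}", paste0(nm, ".csv"))) '
        "else if (is.list(obj)) { for (sub in names(obj)) { el <- obj[[sub]]; "
        "if (is.data.frame(el) || is.matrix(el)) "
        f'write.csv(as.data.frame(el), file.path("{out_dir.as_posix()}", paste0(nm, "_", sub, ".csv"))) }} }}'
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    return sorted(out_dir.glob("*.csv"))
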