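"""Run configuration: parameter dataclasses and key=value config files.

Per-dataset QC thresholds and embedding parameters are free parameters of a
run, so every block validates its own invariants and can be loaded from a
flat INI-style file with one section per stage.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class QCThresholds:
    """Per-cell quality-control bounds; ``None`` leaves a bound unset."""

    min_nreads: float | None = None
    max_nreads: float | None = None
    min_ngenes: float | None = None
    max_ngenes: float | None = None
    max_mito_pc: float | None = None

    def validate(self) -> None:
        for lo, hi in (
            (self.min_nreads, self.max_nreads),
            (self.min_ngenes, self.max_ngenes),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"lower bound {lo} exceeds upper bound {hi}")
        if self.max_mito_pc is not None and not 0 <= self.max_mito_pc <= 100:
            raise ValueError("max_mito_pc must lie in [0, 100]")


@dataclass
class PreprocessParams:
    size_factor: float = 10_000.0
    n_hvg: int = 5_000
    n_mean_bins: int = 20
    scale_clip: float = 10.0
    qc: QCThresholds = field(default_factory=QCThresholds)

    def validate(self) -> None:
        if self.size_factor <= 0:
            raise ValueError("size_factor must be > 0")
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")
        if self.n_mean_bins < 1:
            raise ValueError("n_mean_bins must be >= 1")
        if self.scale_clip <= 0:
            raise ValueError("scale_clip must be > 0")
        self.qc.validate()


@dataclass
class DbmapParams:
    """Diffusion-embedding parameters.

    ``n_components`` (N) structure components are computed over each cell's
    ``n_neighbors`` (K) nearest neighbors; ``min_dist`` (M) and ``spread``
    (S) govern the downstream layout. ``alpha`` is the anisotropy exponent
    (1 approximates the Laplace-Beltrami operator) and ``bandwidth_rank``
    the neighbor rank setting each cell's kernel bandwidth (default
    ceil(K/2)).
    """

    n_components: int = 30
    n_neighbors: int = 15
    min_dist: float = 0.3
    spread: float = 1.0
    metric: str = "euclidean"
    alpha: float = 1.0
    bandwidth_rank: int | None = None

    def validate(self, n_cells: int | None = None) -> None:
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if n_cells is not None and self.n_components >= n_cells:
            raise ValueError("n_components must be < number of cells")
        if n_cells is not None and self.n_neighbors >= n_cells:
            raise ValueError("n_neighbors must be < number of cells")
        if self.min_dist <= 0:
            raise ValueError("min_dist must be > 0")
        if self.spread <= 0:
            raise ValueError("spread must be > 0")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.metric not in ("euclidean", "cosine"):
            raise ValueError("metric must be 'euclidean' or 'cosine'")
        if self.bandwidth_rank is not None and not (
            1 <= self.bandwidth_rank <= self.n_neighbors
        ):
            raise ValueError("bandwidth_rank must lie in [1, n_neighbors]")

    def effective_bandwidth_rank(self) -> int:
        if self.bandwidth_rank is not None:
            return self.bandwidth_rank
        return -(-self.n_neighbors // 2)  # ceil(K/2)


@dataclass
class ClusterParams:
    k: int = 20
    prune: float = 1.0 / 15.0
    resolution: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.prune < 1:
            raise ValueError("prune must lie in [0, 1)")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class TrajectoryParams:
    n_components: int = 10
    k: int = 15
    n_waypoints: int = 500
    t_impute: int = 3
    trend_grid: int = 500
    tol: float = 1e-3

    def validate(self) -> None:
        for name in ("n_components", "k", "n_waypoints", "t_impute", "trend_grid"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class RunConfig:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    dbmap: DbmapParams = field(default_factory=DbmapParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        self.preprocess.validate()
        self.dbmap.validate()
        self.cluster.validate()
        self.trajectory.validate()


def _coerce(value: str, target_type):
    if value.lower() in ("none", ""):
        return None
    if target_type in (int, "int | None", int | None):
        return int(value)
    if target_type in (float, "float | None", float | None):
        return float(value)
    return value


def _fill(obj, section: configparser.SectionProxy) -> None:
    by_name = {f.name: f for f in fields(obj)}
    for key, raw in section.items():
        if key not in by_name:
            raise ValueError(f"unknown config key '{key}' for {type(obj).__name__}")
        f = by_name[key]
        if f.name == "metric" or f.name == "log_level":
            setattr(obj, key, raw)
        elif "int" in str(f.type):
            setattr(obj, key, None if raw.lower() == "none" else int(raw))
        elif "float" in str(f.type):
            setattr(obj, key, None if raw.lower() == "none" else float(raw))
        else:
            setattr(obj, key, raw)


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a flat ``[section] key=value`` file."""
    parser = configparser.ConfigParser()
    read = parser.read(Path(path))
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")
    cfg = RunConfig()
    mapping = {
        "preprocess": cfg.preprocess,
        "qc": cfg.preprocess.qc,
        "dbmap": cfg.dbmap,
        "cluster": cfg.cluster,
        "trajectory": cfg.trajectory,
    }
    for section in parser.sections():
        if section == "run":
            if "seed" in parser[section]:
                cfg.seed = int(parser[section]["seed"])
            if "log_level" in parser[section]:
                cfg.log_level = parser[section]["log_level"]
        elif section in mapping:
            _fill(mapping[section], parser[section])
        else:
            raise ValueError(f"unknown config section [{section}]")
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    parser = configparser.ConfigParser()
    parser["run"] = {"seed": str(cfg.seed), "log_level": cfg.log_level}
    for name, obj in (
        ("preprocess", cfg.preprocess),
        ("qc", cfg.preprocess.qc),
        ("dbmap", cfg.dbmap),
        ("cluster", cfg.cluster),
        ("trajectory", cfg.trajectory),
    ):
        parser[name] = {
            f.name: str(getattr(obj, f.name))
            for f in fields(obj)
            if f.name != "qc" and not isinstance(getattr(obj, f.name), QCThresholds)
        }
    with open(path, "w") as fh:
        parser.write(fh)
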