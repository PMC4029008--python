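"""Mapping the Ca2+ wave-parameter space onto Grover's search database.

A grid of (Gamma, D) parameter points is classified with the wave-regime
rules; the points supporting fast continuous fronts form the solution
subset i_M of a search register (the failure subset i_F collects
saltatory, mixed and failed points, plus any power-of-two padding). The
Grover iteration count over that register realizes the quadratic
search-time bound O(sqrt(D_max/D_C)) against the classical expected
sequential-probe count, and the worked-example velocities let the
quadratic velocity relation v_C >= v_S^2 be checked numerically (in um/s;
the relation is dimensionally inconsistent as stated, so it is recorded as
a flag with a warning, never enforced).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import grover, waves

__all__ = [
    "GridSpec",
    "CorrespondenceConfig",
    "SearchRegister",
    "SearchTime",
    "CorrespondenceReport",
    "build_parameter_grid",
    "build_search_register",
    "algorithmic_search_time",
    "verify_quadratic_relations",
    "run_end_to_end",
]


@dataclass(frozen=True)
class GridSpec:
    """Gamma/D grid over which the register is built.

    D is swept linearly (``geometric`` switches to log spacing) over
    [D_min, D_max]; Gamma follows the continuous-wave index relation
    scaled so the grid stays inside the classifier's Gamma band unless an
    explicit fixed gamma is given.
    """

    D_min: float = 5.0
    D_max: float = 120.0
    n_points: int = 64
    gamma: float = 10.0
    spacing: str = "linear"  # or "geometric"

    def D_values(self) -> np.ndarray:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.spacing == "linear":
            return np.linspace(self.D_min, self.D_max, self.n_points)
        if self.spacing == "geometric":
            return np.geomspace(self.D_min, self.D_max, self.n_points)
        raise ValueError(f"unknown spacing {self.spacing!r}")


@dataclass(frozen=True)
class CorrespondenceConfig:
    """End-to-end pipeline configuration (defaults echo the worked examples)."""

    d: float = 2.0          # um, inter-site spacing
    tau: float = 0.04       # s, release duration
    grid: GridSpec = field(default_factory=GridSpec)
    regime: waves.RegimeConfig = field(default_factory=waves.RegimeConfig)
    D_saltatory_example: float = 15.0   # um^2/s
    D_continuous_example: float = 190.0  # um^2/s

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrespondenceConfig":
        raw = json.loads(Path(path).read_text())
        grid = GridSpec(**raw.pop("grid", {}))
        regime = waves.RegimeConfig(**raw.pop("regime", {}))
        return cls(grid=grid, regime=regime, **raw)


@dataclass
class SearchRegister:
    """Gamma-indexed register partitioned into solutions i_M and failures i_F.

    ``entries`` has one row per index with columns (index, gamma, D, beta,
    regime, is_solution, is_padding). N is a power of two; padding rows are
    always members of i_F.
    """

    entries: pd.DataFrame
    N: int
    M: int

    @property
    def solution_indices(self) -> list[int]:
        return self.entries.loc[self.entries["is_solution"], "index"].tolist()

    @property
    def failure_indices(self) -> list[int]:
        return self.entries.loc[~self.entries["is_solution"], "index"].tolist()

    @property
    def n_qubits(self) -> int:
        return int(round(math.log2(self.N)))

    def oracle(self) -> grover.OracleSpec:
        if self.M == 0:
            raise ValueError("register has an empty solution subset")
        return grover.OracleSpec(self.n_qubits, frozenset(self.solution_indices))


def build_parameter_grid(config: CorrespondenceConfig) -> pd.DataFrame:
    """Materialize the (gamma, D) points of the configured grid."""
    Ds = config.grid.D_values()
    return pd.DataFrame({"gamma": config.grid.gamma, "D": Ds})


def build_search_register(
    points: pd.DataFrame | Sequence[tuple[float, float]],
    config: CorrespondenceConfig | None = None,
) -> SearchRegister:
    """Classify each (gamma, D) point and build the padded register.

    Points classified continuous go to i_M; saltatory/mixed/failure to
    i_F. The register is padded with failure entries up to the next power
    of two; the Gamma <-> index mapping is order-preserving (points are
    indexed in the order given, which the default grid sorts by D).
    An empty solution subset is allowed and simply flagged (M = 0).
    """
    cfg = config or CorrespondenceConfig()
    if not isinstance(points, pd.DataFrame):
        points = pd.DataFrame(points, columns=["gamma", "D"])
    if len(points) == 0:
        raise ValueError("parameter grid must be nonempty")

    rows = []
    for i, (g, D) in enumerate(zip(points["gamma"], points["D"])):
        beta = waves.compute_beta(D, cfg.tau, cfg.d)
        cls = waves.classify_regime(
            waves.DimensionlessState(g, beta), D, cfg.d, cfg.regime
        )
        rows.append(
            {
                "index": i,
                "gamma": float(g),
                "D": float(D),
                "beta": beta,
                "regime": cls.regime,
                "is_solution": cls.regime == "continuous",
                "is_padding": False,
            }
        )
    n_real = len(rows)
    N = 1 << max(1, (n_real - 1).bit_length())
    for i in range(n_real, N):
        rows.append(
            {
                "index": i,
                "gamma": float("nan"),
                "D": float("nan"),
                "beta": float("nan"),
                "regime": "failure",
                "is_solution": False,
                "is_padding": True,
            }
        )
    entries = pd.DataFrame(rows)
    return SearchRegister(entries=entries, N=N, M=int(entries["is_solution"].sum()))


@dataclass(frozen=True)
class SearchTime:
    """Quadratic search-time bound and the exact Grover count for a register."""

    order_bound: int            # ceil(sqrt(D_max/D_C))
    grover_iterations: int | None  # optimal count for the realized register


def algorithmic_search_time(
    D_max: float, D_C: float, register: SearchRegister | None = None
) -> SearchTime:
    """O(sqrt(D_max/D_C)) order bound, plus the realized Grover count.

    The order bound is ceil(sqrt(D_max/D_C)). When a register is supplied,
    the exact optimal iteration count round(pi/(4 asin sqrt(M/N)) - 1/2)
    for its (N, M) is reported alongside (the ceiling formula
    ceil((pi/4) sqrt(N/M)) overstates it by up to one iteration).
    """
    if D_C <= 0:
        raise ValueError("D_C must be > 0")
    if D_max < D_C:
        raise ValueError("require D_max >= D_C")
    bound = math.ceil(math.sqrt(D_max / D_C))
    k = None
    if register is not None and register.M > 0:
        k = grover.optimal_iterations(register.n_qubits, register.M)
    return SearchTime(order_bound=bound, grover_iterations=k)


@dataclass
class CorrespondenceReport:
    """Joint wave/search verification record.

    ``quadratic_relation_holds`` records v_C >= v_S^2 evaluated numerically
    in um/s (dimensionally inconsistent as a law; see warning), and
    ``sqrt_scaling_holds`` whether the classical/Grover query ratio is
    consistent with sqrt(N) scaling. Both are recorded, never enforced.
    """

    classical_queries: float
    grover_queries: int
    search_time_bound: int | None
    velocity_saltatory: float
    velocity_continuous: float
    quadratic_relation_holds: bool
    sqrt_scaling_holds: bool
    warning: str = (
        "v_C >= v_S^2 compares um/s against (um/s)^2 and is checked "
        "numerically in um/s units only"
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def verify_quadratic_relations(
    v_S: float,
    v_C: float,
    classical_queries: float,
    grover_queries: int,
    search_time_bound: int | None = None,
) -> CorrespondenceReport:
    """Record the quadratic velocity and query-count relations.

    The sqrt-scaling flag checks that the Grover count sits within a factor
    of two of (pi/4) sqrt(N) for the register size implied by the classical
    expectation (N = 2*classical - 1 for a single target).
    """
    quad = v_C >= v_S**2
    n_est = max(2.0 * classical_queries - 1.0, 1.0)
    expected_k = (math.pi / 4.0) * math.sqrt(n_est)
    sqrt_ok = grover_queries <= max(2.0 * expected_k, expected_k + 2.0) and (
        grover_queries >= expected_k / 2.0 - 1.0
    )
    return CorrespondenceReport(
        classical_queries=classical_queries,
        grover_queries=grover_queries,
        search_time_bound=search_time_bound,
        velocity_saltatory=v_S,
        velocity_continuous=v_C,
        quadratic_relation_holds=bool(quad),
        sqrt_scaling_holds=bool(sqrt_ok),
    )


def run_end_to_end(
    config: CorrespondenceConfig | None = None,
    seed: int | None = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Sweep, classify, build the register, search, and report.

    Deterministic given ``seed``. Returns a JSON-serializable report; when
    ``out_dir`` is given, also writes register.csv and report.json there.
    A register with no continuous-wave solution is reported with
    ``no_solution = True`` (the search step is skipped).
    """
    cfg = config or CorrespondenceConfig()
    points = build_parameter_grid(cfg)
    register = build_search_register(points, cfg)

    v_S = waves.saltatory_velocity(cfg.D_saltatory_example, cfg.d)
    v_C = waves.continuous_velocity(cfg.D_continuous_example, cfg.tau)
    beta_S = waves.compute_beta(cfg.D_saltatory_example, cfg.tau, cfg.d)
    beta_C = waves.compute_beta(cfg.D_continuous_example, cfg.tau, cfg.d)

    report: dict = {
        "config": {
            "d": cfg.d,
            "tau": cfg.tau,
            "D_min": cfg.grid.D_min,
            "D_max": cfg.grid.D_max,
            "n_points": cfg.grid.n_points,
            "gamma": cfg.grid.gamma,
        },
        "register": {"N": register.N, "M": register.M},
        "worked_examples": {
            "saltatory": {"D": cfg.D_saltatory_example, "beta": beta_S, "v": v_S},
            "continuous": {"D": cfg.D_continuous_example, "beta": beta_C, "v": v_C},
        },
        "no_solution": register.M == 0,
    }

    if register.M > 0:
        solution_D = register.entries.loc[register.entries["is_solution"], "D"]
        D_C_min = float(solution_D.min())
        st = algorithmic_search_time(cfg.grid.D_max, D_C_min, register)
        classical, k = grover.query_count_comparison(register.n_qubits, register.M)
        search = grover.grover_search(register.n_qubits, register.oracle(), seed=seed)
        rep = verify_quadratic_relations(v_S, v_C, classical, k, st.order_bound)
        report["search"] = {
            "order_bound": st.order_bound,
            "grover_iterations": k,
            "classical_expected_queries": classical,
            "success_probability": search.success_probability,
            "measured_index": search.measured,
            "measured_is_solution": search.measured in register.oracle().solution_set,
        }
        report["relations"] = rep.to_dict()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        register.entries.to_csv(out / "register.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
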