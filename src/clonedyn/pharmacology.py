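"""Dose-response processing and drug-combination synergy scoring.

Conventions
-----------
* Viability is normalized to untreated (DMSO) controls; inhibition is
  ``y = 1 - viability`` clipped to [0, 1].
* Monotherapy curves are 4-parameter log-logistic (Hill) functions of dose,
  ``y(x) = lower + (upper - lower) / (1 + (ec50 / x)^slope)``, fitted by
  bounded least squares with a deterministic multi-start grid.
* Resistance is summarized as the relative AUC: trapezoid area of viability
  over log10(dose), divided by the area of a hypothetical non-responder with
  viability 1 across the same dose range, times 100.
* Synergy follows the zero-interaction-potency (ZIP) idea: the expected
  combination inhibition under independence is ``y_a + y_b - y_a*y_b`` from
  the fitted monotherapy curves; each row/column of the combination matrix is
  refitted with the other drug's effect as a fixed floor (potency shift), and
  the ZIP delta is the mean of the two directional refits minus the
  independence expectation.  The plate summary is the mean of the nine
  highest delta values (optionally the most-synergistic contiguous 3x3
  window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InputError

__all__ = [
    "DoseResponseCurve",
    "DoseResponseMatrix",
    "LogLogisticFit",
    "SynergyResult",
    "Synergy3DResult",
    "normalize_viability",
    "relative_auc",
    "fit_loglogistic",
    "zip_delta",
    "zip_delta_3d",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class DoseResponseCurve:
    """Monotherapy viability curve over a dose series (molar units)."""

    drug: str
    concentrations: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.shape != self.viability.shape:
            raise InputError("concentration/viability length mismatch")
        if len(np.unique(self.concentrations)) != self.concentrations.size:
            raise InputError("concentrations must be distinct")
        if not np.all(np.isfinite(self.viability)):
            raise InputError("viability values must be finite")


@dataclass
class DoseResponseMatrix:
    """6x6 (or larger) viability grid over two drug concentration axes.

    Axes are stored ascending with the zero (DMSO) dose first; ``viability``
    has shape (len(conc_b), len(conc_a)), rows indexed by drug B dose.  For
    3-D stacks, ``conc_c`` records the fixed third-drug dose of this layer.
    """

    drug_a: str
    drug_b: str
    conc_a: np.ndarray
    conc_b: np.ndarray
    viability: np.ndarray
    drug_c: Optional[str] = None
    conc_c: Optional[float] = None

    def __post_init__(self) -> None:
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.shape != (self.conc_b.size, self.conc_a.size):
            raise InputError("viability grid shape does not match dose axes")
        for name, axis in (("conc_a", self.conc_a), ("conc_b", self.conc_b)):
            if axis[0] != 0.0:
                raise InputError(f"{name} must include the zero (DMSO) dose first")
            if np.any(np.diff(axis) <= 0):
                raise InputError(f"{name} must be strictly ascending")

    def normalized(self) -> "DoseResponseMatrix":
        """Divide the grid by the double-DMSO well so viability(0,0) == 1."""
        ref = self.viability[0, 0]
        if ref <= 0:
            raise InputError("DMSO reference well must be positive")
        return DoseResponseMatrix(
            self.drug_a, self.drug_b, self.conc_a, self.conc_b,
            self.viability / ref, self.drug_c, self.conc_c,
        )

    # -- plate CSV dialect: header row/column carry doses in molar units;
    # orientation="paper" mirrors the bench layout (DMSO top-left, doses
    # increasing left->right and top->bottom).
    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# drug_a={self.drug_a} drug_b={self.drug_b}")
            if self.conc_c is not None:
                fh.write(f" drug_c={self.drug_c} conc_c={self.conc_c:g}")
            fh.write("\n")
            fh.write("b\\a," + ",".join(f"{c:g}" for c in self.conc_a) + "\n")
            for j, cb in enumerate(self.conc_b):
                row = ",".join(f"{v:.6g}" for v in self.viability[j])
                fh.write(f"{cb:g},{row}\n")

    @classmethod
    def from_csv(cls, path, orientation: str = "paper") -> "DoseResponseMatrix":
        drug_a, drug_b, drug_c, conc_c = "drug_a", "drug_b", None, None
        rows: list[list[float]] = []
        conc_a: list[float] = []
        conc_b: list[float] = []
        try:
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if not line:
                        continue
                    if line.startswith("#"):
                        for tok in line[1:].split():
                            if "=" in tok:
                                k, v = tok.split("=", 1)
                                if k == "drug_a":
                                    drug_a = v
                                elif k == "drug_b":
                                    drug_b = v
                                elif k == "drug_c":
                                    drug_c = v
                                elif k == "conc_c":
                                    conc_c = float(v)
                        continue
                    cells = line.split(",")
                    if cells[0].startswith("b\\a") or cells[0] in ("", "b/a"):
                        conc_a = [float(c) for c in cells[1:]]
                        continue
                    conc_b.append(float(cells[0]))
                    rows.append([float(c) for c in cells[1:]])
        except (OSError, ValueError) as exc:
            raise InputError(f"cannot parse plate CSV {path}: {exc}") from exc
        if not rows or not conc_a:
            raise InputError(f"plate CSV {path} has no dose grid")
        grid = np.asarray(rows, dtype=float)
        ca, cb = np.asarray(conc_a), np.asarray(conc_b)
        if orientation == "reversed":  # doses decreasing in the file
            ca, cb, grid = ca[::-1], cb[::-1], grid[::-1, ::-1]
        elif orientation != "paper":
            raise InputError(f"unknown plate orientation {orientation!r}")
        return cls(drug_a, drug_b, ca, cb, grid, drug_c, conc_c)


# ---------------------------------------------------------------------------
# normalization and AUC


def normalize_viability(raw, untreated) -> np.ndarray:
    """Divide plate readings by the mean untreated (DMSO) reading."""
    untreated = np.asarray(untreated, dtype=float)
    ref = float(np.mean(untreated))
    if ref <= 0:
        raise InputError("mean untreated signal must be positive")
    return np.asarray(raw, dtype=float) / ref


def relative_auc(curve: DoseResponseCurve) -> float:
    """Relative AUC in percent: 100 * trapezoid(viability over log10 dose) /
    trapezoid of a constant non-responder (viability 1) on the same axis.

    Zero doses carry no log coordinate and are excluded from the axis.
    """
    mask = curve.concentrations > 0
    conc = curve.concentrations[mask]
    via = curve.viability[mask]
    if conc.size < 2:
        raise InputError("need at least two positive concentrations")
    order = np.argsort(conc)
    x = np.log10(conc[order])
    y = via[order]
    width = x[-1] - x[0]
    if width <= 0:
        raise InputError("degenerate dose range")
    return float(100.0 * np.trapezoid(y, x) / width)


# ---------------------------------------------------------------------------
# log-logistic fitting


@dataclass
class LogLogisticFit:
    """Fitted 4-parameter log-logistic inhibition curve (Results object)."""

    lower: float
    upper: float
    ec50: float
    slope: float
    flipped: bool = False
    fallback: bool = False
    residual_ss: float = 0.0

    def inhibition(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, self.lower, dtype=float)
        pos = x > 0
        out[pos] = self.lower + (self.upper - self.lower) / (
            1.0 + (self.ec50 / x[pos]) ** self.slope
        )
        return out

    def summary(self) -> str:
        tag = " (flipped)" if self.flipped else ""
        tag += " (constant fallback)" if self.fallback else ""
        return (
            f"log-logistic fit{tag}: lower={self.lower:.4f} upper={self.upper:.4f} "
            f"ec50={self.ec50:.4g} M slope={self.slope:.3f} ss={self.residual_ss:.3g}"
        )


def _ll_model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    lower, upper, log_ec50, slope = params
    return lower + (upper - lower) / (1.0 + (10.0 ** log_ec50 / x) ** slope)


def fit_loglogistic(
    concentrations: Sequence[float],
    responses: Sequence[float],
    expect_inhibition: bool = True,
) -> LogLogisticFit:
    """Bounded least-squares 4PL fit of inhibition vs dose.

    Deterministic multi-start over a slope/EC50 grid; EC50 constrained to the
    tested dose range times [1e-2, 1e2].  A monotone-decreasing response is
    taken as viability passed by mistake: it is flipped to ``1 - y`` with a
    warning and the ``flipped`` flag set.  A constant response short-circuits
    to a fixed-effect fallback.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise InputError("concentration/response length mismatch")
    mask = x > 0
    x, y = x[mask], y[mask]
    if np.unique(x).size < 4:
        raise InputError("need >= 4 distinct nonzero concentrations")

    flipped = False
    if expect_inhibition and np.ptp(y) > 1e-9:
        trend = np.polyfit(np.log10(x), y, 1)[0]
        if trend < 0:
            warnings.warn(
                "response decreases with dose; assuming viability convention "
                "and fitting 1 - response",
                stacklevel=2,
            )
            y = 1.0 - y
            flipped = True

    geo_mid = float(np.sqrt(x.min() * x.max()))
    if np.ptp(y) < 1e-9:  # degenerate constant response
        level = float(np.clip(np.mean(y), 0.0, 1.0))
        return LogLogisticFit(level, level, geo_mid, 1.0, flipped=flipped, fallback=True)

    lo_ec, hi_ec = np.log10(x.min() * 1e-2), np.log10(x.max() * 1e2)
    bounds = (np.array([0.0, 0.0, lo_ec, 0.1]), np.array([1.0, 1.0, hi_ec, 20.0]))
    y0 = float(np.clip(y.min(), 0, 1))
    y1 = float(np.clip(y.max(), 0, 1))
    best = None
    for slope0 in (0.5, 1.0, 2.0, 4.0):
        for lec0 in np.linspace(np.log10(x.min()), np.log10(x.max()), 3):
            p0 = np.clip(
                np.array([y0, y1, lec0, slope0]),
                bounds[0] + 1e-12,
                bounds[1] - 1e-12,
            )
            try:
                res = least_squares(
                    lambda p: _ll_model(p, x) - y,
                    p0,
                    bounds=bounds,
                    ftol=1e-15,
                    xtol=1e-15,
                    gtol=1e-15,
                    max_nfev=2000,
                )
            except Exception:  # pragma: no cover - scipy internal failure
                continue
            if best is None or res.cost < best.cost - 1e-18:
                best = res
            if best.cost < 1e-18:  # exact fit found; grid exhausted pointlessly
                break
        if best is not None and best.cost < 1e-18:
            break
    if best is None:  # pragma: no cover
        raise InputError("log-logistic fit failed on all starts")
    lower, upper, lec, slope = best.x
    return LogLogisticFit(
        float(lower), float(upper), float(10.0 ** lec), float(slope),
        flipped=flipped, residual_ss=float(2 * best.cost),
    )


def _fit_shifted(
    x: np.ndarray, y: np.ndarray, floor: float
) -> Optional[Callable[[np.ndarray], np.ndarray]]:
    """Potency-shifted refit: log-logistic with lower asymptote fixed at
    ``floor`` and upper free in [floor, 1].  Returns an evaluator or None
    when no stable fit exists (caller falls back to observed values)."""
    if floor >= 0.999:
        return None
    lo_ec, hi_ec = np.log10(x.min() * 1e-2), np.log10(x.max() * 1e2)
    bounds = (np.array([floor, lo_ec, 0.1]), np.array([1.0, hi_ec, 20.0]))

    def model(p, xx):
        upper, lec, slope = p
        return floor + (upper - floor) / (1.0 + (10.0 ** lec / xx) ** slope)

    if np.ptp(y) < 1e-9:
        level = float(np.clip(np.mean(y), floor, 1.0))
        return lambda xx: np.full(np.asarray(xx, dtype=float).shape, level)

    best = None
    up0 = float(np.clip(y.max(), floor + 1e-6, 1.0))
    for slope0 in (0.5, 1.0, 2.0, 4.0):
        for lec0 in np.linspace(np.log10(x.min()), np.log10(x.max()), 2):
            p0 = np.clip(
                np.array([up0, lec0, slope0]), bounds[0] + 1e-12, bounds[1] - 1e-12
            )
            try:
                res = least_squares(
                    lambda p: model(p, x) - y,
                    p0,
                    bounds=bounds,
                    ftol=1e-14,
                    xtol=1e-14,
                    gtol=1e-14,
                    max_nfev=1000,
                )
            except Exception:  # pragma: no cover
                continue
            if best is None or res.cost < best.cost - 1e-18:
                best = res
            if best.cost < 1e-18:
                break
        if best is not None and best.cost < 1e-18:
            break
    if best is None:  # pragma: no cover
        return None
    params = best.x.copy()
    return lambda xx: model(params, np.asarray(xx, dtype=float))


# ---------------------------------------------------------------------------
# ZIP synergy


@dataclass
class SynergyResult:
    """ZIP delta surface over the nonzero-dose grid plus its top-9 summary."""

    delta: pd.DataFrame  # index: conc_b > 0, columns: conc_a > 0
    summary: float
    fit_a: LogLogisticFit
    fit_b: LogLogisticFit
    conc_c: Optional[float] = None
    flags: list[str] = field(default_factory=list)

    def summary_text(self) -> str:
        lines = [
            f"ZIP synergy: summary (mean of 9 highest deltas) = {self.summary:.4f}",
            f"  drug A: {self.fit_a.summary()}",
            f"  drug B: {self.fit_b.summary()}",
        ]
        if self.flags:
            lines.append("  flags: " + "; ".join(self.flags))
        return "\n".join(lines)


@dataclass
class Synergy3DResult:
    layers: list[SynergyResult]
    cube: np.ndarray  # (n_layers, n_b, n_a) deviation cube
    conc_c: np.ndarray


def _top9_summary(delta: np.ndarray, mode: str) -> float:
    flat = delta.ravel()
    if mode == "top9":
        k = min(9, flat.size)
        return float(np.sort(flat)[-k:].mean())
    if mode == "window3x3":
        nb, na = delta.shape
        if nb < 3 or na < 3:
            return float(flat.mean())
        best = -np.inf
        for i in range(nb - 2):
            for j in range(na - 2):
                best = max(best, float(delta[i : i + 3, j : j + 3].mean()))
        return best
    raise InputError(f"unknown summary mode {mode!r}")


def zip_delta(matrix: DoseResponseMatrix, summary_mode: str = "top9") -> SynergyResult:
    """ZIP synergy scoring of one normalized 6x6 viability matrix.

    Requires the monotherapy row (conc_b = 0) and column (conc_a = 0).
    Unfittable axes fall back to interpolated (observed) monotherapy
    effects, recorded in ``flags``.
    """
    if abs(matrix.viability[0, 0] - 1.0) > 0.05:
        raise InputError("matrix must be normalized (viability at (0,0) == 1)")
    flags: list[str] = []
    inh = np.clip(1.0 - matrix.viability, 0.0, 1.0)
    a = matrix.conc_a[1:]
    b = matrix.conc_b[1:]
    if a.size == 0 or b.size == 0:
        raise InputError("missing monotherapy axis")
    mono_a = inh[0, 1:]
    mono_b = inh[1:, 0]

    def _mono_fit(conc, y, label):
        try:
            return fit_loglogistic(conc, y)
        except InputError:
            flags.append(f"monotherapy {label} unfittable; using observed effects")
            level = float(np.clip(np.mean(y), 0, 1))
            return LogLogisticFit(level, level, float(np.sqrt(conc.min() * conc.max())),
                                  1.0, fallback=True)

    fit_a = _mono_fit(a, mono_a, "A")
    fit_b = _mono_fit(b, mono_b, "B")
    ya = mono_a if fit_a.fallback and np.ptp(mono_a) > 1e-9 else fit_a.inhibition(a)
    yb = mono_b if fit_b.fallback and np.ptp(mono_b) > 1e-9 else fit_b.inhibition(b)

    expected = ya[None, :] + yb[:, None] - ya[None, :] * yb[:, None]

    y_row = np.empty((b.size, a.size))
    for j in range(b.size):
        obs = inh[j + 1, 1:]
        fn = _fit_shifted(a, obs, float(yb[j]))
        if fn is None:
            flags.append(f"row refit at conc_b={b[j]:g} fell back to observed")
            y_row[j, :] = obs
        else:
            y_row[j, :] = fn(a)

    y_col = np.empty((b.size, a.size))
    for i in range(a.size):
        obs = inh[1:, i + 1]
        fn = _fit_shifted(b, obs, float(ya[i]))
        if fn is None:
            flags.append(f"column refit at conc_a={a[i]:g} fell back to observed")
            y_col[:, i] = obs
        else:
            y_col[:, i] = fn(b)

    delta = 0.5 * (y_row + y_col) - expected
    return SynergyResult(
        delta=pd.DataFrame(delta, index=b, columns=a),
        summary=_top9_summary(delta, summary_mode),
        fit_a=fit_a,
        fit_b=fit_b,
        conc_c=matrix.conc_c,
        flags=flags,
    )


def zip_delta_3d(
    stack: Sequence[DoseResponseMatrix], summary_mode: str = "top9"
) -> Synergy3DResult:
    """Layered ZIP scoring for a third-drug dose stack.

    Each layer is a 6x6 A x B matrix at a fixed dose of drug C, normalized to
    the global (triple-DMSO-equivalent) control.  The layer's (0,0) well then
    reads drug C monotherapy, whose inhibition ``y_c`` is folded into the
    independence baseline ``1 - (1-y_a)(1-y_b)(1-y_c)`` and into the floors of
    the directional refits.
    """
    if len(stack) < 2:
        raise InputError("need at least two layers")
    ref = stack[0]
    for layer in stack[1:]:
        if not (
            np.array_equal(layer.conc_a, ref.conc_a)
            and np.array_equal(layer.conc_b, ref.conc_b)
        ):
            raise InputError("inconsistent dose axes across layers")
    layers = sorted(stack, key=lambda m: (m.conc_c if m.conc_c is not None else 0.0))
    a = ref.conc_a[1:]
    b = ref.conc_b[1:]
    results: list[SynergyResult] = []
    cube = np.empty((len(layers), b.size, a.size))
    for li, layer in enumerate(layers):
        flags: list[str] = []
        inh = np.clip(1.0 - layer.viability, 0.0, 1.0)
        yc = float(inh[0, 0])
        if yc >= 0.999:
            raise InputError("third drug saturates the layer; no signal left")
        # back out A/B monotherapy from the C-containing control row/column
        adj_a = np.clip((inh[0, 1:] - yc) / (1.0 - yc), 0.0, 1.0)
        adj_b = np.clip((inh[1:, 0] - yc) / (1.0 - yc), 0.0, 1.0)
        fit_a = fit_loglogistic(a, adj_a)
        fit_b = fit_loglogistic(b, adj_b)
        ya = fit_a.inhibition(a)
        yb = fit_b.inhibition(b)
        expected = 1.0 - np.outer(1.0 - yb, 1.0 - ya) * (1.0 - yc)

        y_row = np.empty((b.size, a.size))
        for j in range(b.size):
            floor = 1.0 - (1.0 - yb[j]) * (1.0 - yc)
            fn = _fit_shifted(a, inh[j + 1, 1:], float(floor))
            y_row[j, :] = inh[j + 1, 1:] if fn is None else fn(a)
            if fn is None:
                flags.append(f"row refit at conc_b={b[j]:g} fell back to observed")
        y_col = np.empty((b.size, a.size))
        for i in range(a.size):
            floor = 1.0 - (1.0 - ya[i]) * (1.0 - yc)
            fn = _fit_shifted(b, inh[1:, i + 1], float(floor))
            y_col[:, i] = inh[1:, i + 1] if fn is None else fn(b)
            if fn is None:
                flags.append(f"column refit at conc_a={a[i]:g} fell back to observed")

        delta = 0.5 * (y_row + y_col) - expected
        cube[li] = delta
        results.append(
            SynergyResult(
                delta=pd.DataFrame(delta, index=b, columns=a),
                summary=_top9_summary(delta, summary_mode),
                fit_a=fit_a,
                fit_b=fit_b,
                conc_c=layer.conc_c,
                flags=flags,
            )
        )
    conc_c = np.array([m.conc_c if m.conc_c is not None else np.nan for m in layers])
    return Synergy3DResult(layers=results, cube=cube, conc_c=conc_c)
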