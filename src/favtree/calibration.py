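"""16S rDNA substitution rates and the tan(theta) -> S calibration curve.

The substitution rate S of a pairwise-aligned 16S rDNA pair is the percent
of differing sites among columns where neither sequence has a gap or an
ambiguity code. Plotting S against tan(theta) for many genome pairs gives a
curved relation which is fit by

    S = const1 * (exp(const2 * tan_theta) - 1)        (default form)
    S = const1 *  exp(const2 * tan_theta)             (form="exp")

The default form forces S(0) = 0: identical genomes must show zero 16S
divergence. The fitted model converts any tan(theta) into an F value on the
same percent-substitution scale, which is what the distance matrices and
trees are built from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

FORMS = ("exp_minus_one", "exp")

_VALID_BASES = frozenset("ACGT")


@dataclass
class SubstitutionRate:
    pair: tuple[str, str]
    s: float  # percent substituted sites
    compared_sites: int
    substituted_sites: int


def substitution_rate(
    seq_a: str, seq_b: str, pair: tuple[str, str] = ("a", "b")
) -> SubstitutionRate:
    """Percent substitutions per site over ungapped, unambiguous columns.

    Columns containing a gap or an ambiguity code (anything outside ACGT
    after U->T) in either sequence are excluded. Symmetric in its arguments.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}")
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    compared = 0
    substituted = 0
    for ca, cb in zip(a, b):
        if ca in _VALID_BASES and cb in _VALID_BASES:
            compared += 1
            if ca != cb:
                substituted += 1
    if compared == 0:
        raise ValueError(f"no comparable (ungapped, unambiguous) columns for pair {pair}")
    return SubstitutionRate(pair, 100.0 * substituted / compared, compared, substituted)


@dataclass
class CalibrationModel:
    """Fitted (or preset) tan(theta) -> S regression."""

    const1: float
    const2: float
    r_squared: float
    form: str = "exp_minus_one"
    convention: str = "angle"

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {FORMS}")

    def predict(self, tan_theta: float) -> float:
        """S (or F) value at a given tan(theta); strictly increasing."""
        t = float(tan_theta)
        if not -1e-9 <= t <= 1 + 1e-9:
            raise ValueError(f"tan_theta must lie in [0, 1], got {t}")
        t = min(max(t, 0.0), 1.0)
        if self.form == "exp_minus_one":
            return self.const1 * (math.exp(self.const2 * t) - 1.0)
        return self.const1 * math.exp(self.const2 * t)

    def inverse(self, s: float) -> float:
        """tan(theta) that maps to a given S; the exact inverse of predict."""
        if self.form == "exp_minus_one":
            if s < 0:
                raise ValueError(f"S must be non-negative, got {s}")
            return math.log(s / self.const1 + 1.0) / self.const2
        if s <= 0:
            raise ValueError(f"S must be positive under the pure exponential form, got {s}")
        return math.log(s / self.const1) / self.const2


def _model_fn(form: str):
    if form == "exp_minus_one":
        return lambda t, a, b: a * (np.exp(b * t) - 1.0)
    return lambda t, a, b: a * np.exp(b * t)


def fit_calibration(
    pairs: Sequence[tuple[float, float]],
    form: str = "exp_minus_one",
    convention: str = "angle",
) -> CalibrationModel:
    """Least-squares fit of the calibration curve on the untransformed S scale.

    All supplied data points are used, including duplicates from multiple
    16S copies per genome and from the two query/reference orientations of
    each genome pair. R-squared is computed on the original S scale.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 (tan_theta, S) pairs, got {len(pairs)}")
    t = np.asarray([p[0] for p in pairs], dtype=float)
    s = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("tan_theta values must lie in [0, 1]")
    if np.any(s < 0):
        raise ValueError("S values must be non-negative")
    if np.ptp(t) == 0:
        raise ValueError("degenerate data: all tan_theta values are equal")
    p0 = (max(s.max(), 1e-6) / math.e, 1.0)
    try:
        popt, _ = curve_fit(_model_fn(form), t, s, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"calibration fit did not converge from initial values const1={p0[0]:.6g}, "
            f"const2={p0[1]:.6g} within 20000 evaluations: {exc}"
        ) from exc
    fitted = _model_fn(form)(t, *popt)
    ss_res = float(np.sum((s - fitted) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationModel(float(popt[0]), float(popt[1]), r2, form=form, convention=convention)


def tantheta_to_S(model: CalibrationModel, tan_theta: float, convention: str | None = None) -> float:
    """Evaluate the calibration model, guarding against convention mixups."""
    if convention is not None and convention != model.convention:
        raise ValueError(
            f"convention mismatch: model fitted under {model.convention!r}, input is {convention!r}"
        )
    return model.predict(tan_theta)


#: Published constants of the original 55-species calibration, usable without
#: calibration data. Convention-dependent: treat as the package-default
#: "angle" convention unless refit.
PRESETS = {
    "satoh2013": CalibrationModel(
        const1=5.0112, const2=2.2223, r_squared=0.9366, form="exp_minus_one", convention="angle"
    )
}


def preset(name: str = "satoh2013") -> CalibrationModel:
    try:
        model = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return CalibrationModel(model.const1, model.const2, model.r_squared, model.form, model.convention)


def save_model(model: CalibrationModel, path: str | Path) -> None:
    Path(path).write_text(
        f"form = {model.form}\nconvention = {model.convention}\n"
        f"const1 = {model.const1:.10g}\nconst2 = {model.const2:.10g}\n"
        f"r_squared = {model.r_squared:.10g}\n"
    )


def load_model(path: str | Path) -> CalibrationModel:
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    return CalibrationModel(
        const1=float(kv["const1"]),
        const2=float(kv["const2"]),
        r_squared=float(kv.get("r_squared", "nan")),
        form=kv.get("form", "exp_minus_one"),
        convention=kv.get("convention", "angle"),
    )
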