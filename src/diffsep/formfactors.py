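"""Atomic X-ray form factors as sum-of-Gaussians parameterizations.

f(q) = sum_k a_k * exp(-b_k * (q / 4 pi)^2) + c,  q = |Q| in inverse angstrom,

the standard crystallographic four-Gaussian fit (a_k, c in electrons, b_k in
square angstrom), with coefficients transcribed from the International Tables
for Crystallography Vol. C analytical fits so the package needs no external
coefficient files.  At q = 0 the value approaches the electron count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FormFactorCoefficients", "FORM_FACTORS", "atomic_form_factor"]


@dataclass(frozen=True)
class FormFactorCoefficients:
    element: str
    gaussian_amplitudes: tuple[float, ...]  # a_k, electrons
    gaussian_widths: tuple[float, ...]  # b_k, square angstrom
    constant: float  # c, electrons
    n_electrons: int

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.gaussian_widths):
            raise ValueError(f"{self.element}: negative Gaussian width")
        total = sum(self.gaussian_amplitudes) + self.constant
        if abs(total - self.n_electrons) > 0.02 * self.n_electrons:
            raise ValueError(
                f"{self.element}: f(0) = {total:.4f} deviates more than 2% "
                f"from Z = {self.n_electrons}"
            )

    def __call__(self, q) -> np.ndarray:
        return atomic_form_factor(self, q)


def _ff(element, z, a, b, c):
    return FormFactorCoefficients(element, tuple(a), tuple(b), c, z)


# International Tables Vol. C, Table 6.1.1.4 four-Gaussian coefficients.
FORM_FACTORS: dict[str, FormFactorCoefficients] = {
    f.element: f
    for f in [
        _ff("H", 1, (0.489918, 0.262003, 0.196767, 0.049879),
            (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
        _ff("C", 6, (2.31000, 1.02000, 1.58860, 0.865000),
            (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
        _ff("N", 7, (12.2126, 3.13220, 2.01250, 1.16630),
            (0.005700, 9.89330, 28.9975, 0.582600), -11.5290),
        _ff("O", 8, (3.04850, 2.28680, 1.54630, 0.867000),
            (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
        _ff("F", 9, (3.53920, 2.64120, 1.51700, 1.02430),
            (10.2825, 4.29440, 0.261500, 26.1476), 0.277600),
        _ff("P", 15, (6.43450, 4.17910, 1.78000, 1.49080),
            (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
        _ff("S", 16, (6.90530, 5.20340, 1.43790, 1.58630),
            (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
        _ff("Cl", 17, (11.4604, 7.19640, 6.25560, 1.64550),
            (0.010400, 1.16620, 18.5194, 47.7784), -9.55740),
        _ff("Br", 35, (17.1789, 5.23580, 5.63770, 3.98510),
            (2.17230, 16.5796, 0.260900, 41.4328), 2.95570),
    ]
}


def atomic_form_factor(coeffs: FormFactorCoefficients, q_magnitude) -> np.ndarray:
    """Evaluate f(q) in electrons at scattering-vector magnitude q (1/angstrom).

    Accepts scalars or arrays; raises on negative q.
    """
    q = np.asarray(q_magnitude, dtype=float)
    if np.any(q < 0):
        raise ValueError("q magnitude must be non-negative")
    s2 = (q / (4.0 * np.pi)) ** 2
    a = np.asarray(coeffs.gaussian_amplitudes)
    b = np.asarray(coeffs.gaussian_widths)
    f = np.tensordot(np.exp(-np.multiply.outer(s2, b)), a, axes=([-1], [0]))
    f = f + coeffs.constant
    return f if f.shape else float(f)
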