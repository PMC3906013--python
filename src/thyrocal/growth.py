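"""Age- and sex-specific thyroid mass assignment.

Thyroid masses are not measured per subject; each subject is assigned the
population-median mass for their age and sex from a growth table built on
ultrasound volumetry of children aged 5-16, so the residual subject-level
variation acts as Berkson error around the assignment.  Ages outside the
table are filled by linear interpolation/extrapolation on log-mass, floored
at a configurable minimum.
"""

from __future__ import annotations

import numpy as np

# median thyroid mass (g) by age, per sex; ages 5..16
DEFAULT_GROWTH_TABLE: dict[str, dict[float, float]] = {
    "male": {
        5: 3.6, 6: 4.1, 7: 4.6, 8: 5.2, 9: 5.9, 10: 6.7,
        11: 7.6, 12: 8.6, 13: 9.8, 14: 11.1, 15: 12.6, 16: 14.2,
    },
    "female": {
        5: 3.4, 6: 3.9, 7: 4.5, 8: 5.1, 9: 5.8, 10: 6.7,
        11: 7.7, 12: 8.9, 13: 10.2, 14: 11.6, 15: 13.0, 16: 14.4,
    },
}

MASS_FLOOR_G = 1.0


def assign_mass(e, sex, growth_table: dict | None = None,
                mass_floor: float = MASS_FLOOR_G) -> np.ndarray:
    """Deterministic assigned thyroid mass (g) at age-at-exposure ``e``.

    Log-mass is interpolated linearly between table ages (so mid-age values
    are geometric means of the neighbours) and extrapolated linearly outside
    the table range, then floored at ``mass_floor``.
    """
    if growth_table is None:
        growth_table = DEFAULT_GROWTH_TABLE
    e = np.atleast_1d(np.asarray(e, dtype=float))
    sex = np.atleast_1d(np.asarray(sex))
    if np.any((e < 0) | (e >= 18)):
        raise ValueError("age at exposure must be in [0, 18)")
    out = np.empty_like(e)
    for s in np.unique(sex):
        tab = growth_table.get(str(s))
        if not tab:
            raise ValueError(f"growth table missing entries for sex {s!r}")
        ages = np.array(sorted(tab))
        logm = np.log(np.array([tab[age] for age in ages]))
        mask = sex == s
        x = e[mask]
        y = np.interp(x, ages, logm)
        # linear extrapolation on log-mass beyond the table range
        lo, hi = ages[0], ages[-1]
        slope_lo = (logm[1] - logm[0]) / (ages[1] - ages[0])
        slope_hi = (logm[-1] - logm[-2]) / (ages[-1] - ages[-2])
        y = np.where(x < lo, logm[0] + slope_lo * (x - lo), y)
        y = np.where(x > hi, logm[-1] + slope_hi * (x - hi), y)
        out[mask] = np.exp(y)
    return np.maximum(out, mass_floor)
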