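"""Independent scalar oracles for the CSF pipeline.

Everything here is written from the closed-form definitions using only the
``math`` module, with no imports from the package under test and no shared
helpers: each oracle is a direct scalar composition of the formulas. Used
to cross-check the vectorised implementation.
"""

import math


def oracle_pupil(age, luminance, area, eyes):
    x = (luminance * area * (1.0 if eyes == 2 else 0.1) / 846.0) ** 0.41
    base = 7.75 - 5.75 * x / (x + 2.0)
    return base + (age - 28.58) * (0.02132 - 0.009562 * base)


def oracle_inhibition_cutoff(age, e, u0=7.0):
    # normalised ganglion density profile at eccentricity e
    a = -0.404 * math.exp(-0.01246 * age) - 0.1792 * math.exp(0.01525 * age)
    ratio = 0.85 / (1.0 + (e / a) ** 2) + 0.15 / (1.0 + (e / 7.3) ** 2)
    bracket = 0.85 / (1.0 + (e / 4.0) ** 2) + 0.13 / (1.0 + (e / 20.0) ** 2) + 0.02
    return u0 * ratio / math.sqrt(bracket)


def oracle_neural_noise(age, e, phi0=3e-8):
    a = -0.404 * math.exp(-0.01246 * age) - 0.1792 * math.exp(0.01525 * age)
    ratio = 0.85 / (1.0 + (e / a) ** 2) + 0.15 / (1.0 + (e / 7.3) ** 2)
    return phi0 / ratio


def oracle_csf_barten(
    u,
    luminance,
    field_x,
    field_y,
    eyes=1,
    sigma0=0.5,
    eta=0.03,
    k=3.0,
    u_opt=60.0,
    cab=0.08,
    u0=7.0,
    phi0=3e-8,
    te=0.1,
    to=math.inf,
    p=1.285e6,
    pupil=None,
):
    """Foveal age-independent CSF, one scalar composition."""
    if pupil is None:
        x = (luminance * field_x * field_y * (1.0 if eyes == 2 else 0.1) / 846.0) ** 0.41
        pupil = 7.75 - 5.75 * x / (x + 2.0)
    illum = (math.pi * luminance * pupil**2 / 4.0) * (
        1.0 - (pupil / 9.7) ** 2 + (pupil / 12.4) ** 4
    )
    phi_opt = 1.0 / (eta * p * illum)
    sigma_opt = math.sqrt(sigma0**2 + (cab * pupil) ** 2)
    mopt = math.exp(-2.0 * math.pi**2 * sigma_opt**2 * (u / u_opt) ** 2)
    mlat_sq = 1.0 - math.exp(-((u / u0) ** 2))
    if mlat_sq == 0.0:
        return 0.0
    t = min(te, to)
    return (
        mopt
        / k
        * math.sqrt(field_x * field_y * t / (2.0 * (phi_opt + phi0 / mlat_sq)))
    )


def oracle_csf_spatial(
    u,
    age,
    luminance,
    field_x,
    field_y,
    eyes=2,
    eccentricity=0.0,
    te=0.1,
    to=math.inf,
    u0=7.0,
    phi0=3e-8,
    cab=0.08,
    p=1.285e6,
):
    """Full age-dependent CSF, one scalar composition of every stage."""
    # fitted age curves
    sigma0 = 0.42 + 0.26 * (1.0 - math.exp(-(((age - 17.0) / 27.1837) ** 1.547)))
    if age == 17.0:
        eta = 0.042
    else:
        eta = 0.019 + 0.023 * (1.0 - math.exp(-(((age - 17.0) / 13.0645) ** -1.753)))
    k = 3.0 if age <= 50.0 else 4.0
    u_opt = 35.0 if age <= 50.0 else 30.0
    # pupil and retinal illuminance
    area = field_x * field_y
    x = (luminance * area * (1.0 if eyes == 2 else 0.1) / 846.0) ** 0.41
    base = 7.75 - 5.75 * x / (x + 2.0)
    pupil = base + (age - 28.58) * (0.02132 - 0.009562 * base)
    illum = (math.pi * luminance * pupil**2 / 4.0) * (
        1.0 - (pupil / 9.7) ** 2 + (pupil / 12.4) ** 4
    )
    phi_opt = 1.0 / (eta * p * illum)
    # optical MTF
    sigma_opt = math.sqrt(sigma0**2 + (cab * pupil) ** 2)
    mopt = math.exp(-2.0 * math.pi**2 * sigma_opt**2 * (u / u_opt) ** 2)
    # neural stage at eccentricity
    e = eccentricity
    a = -0.404 * math.exp(-0.01246 * age) - 0.1792 * math.exp(0.01525 * age)
    ratio = 0.85 / (1.0 + (e / a) ** 2) + 0.15 / (1.0 + (e / 7.3) ** 2)
    bracket = 0.85 / (1.0 + (e / 4.0) ** 2) + 0.13 / (1.0 + (e / 20.0) ** 2) + 0.02
    u_inh = u0 * ratio / math.sqrt(bracket)
    phi_neu = phi0 / ratio
    mlat_sq = 1.0 - math.exp(-((u / u_inh) ** 2))
    if mlat_sq == 0.0:
        return 0.0
    t = min(te, to)
    return (
        mopt
        / k
        * math.sqrt(field_x * field_y * t / (2.0 * (phi_opt + phi_neu / mlat_sq)))
    )
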