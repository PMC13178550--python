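"""Independent straight-line reimplementation of the heat-budget
equations, used only as a cross-check oracle.  Deliberately shares no
code with the package: every function is the printed formula typed out
once, with no validation, composition or constants imported."""

import math


def bsa(mass, height, h_exp=0.725):
    return 0.202 * mass**0.425 * height**h_exp


def psat_kpa(T):
    return 10.0 ** (8.07131 - 1730.63 / (233.426 + T)) * 101.325 / 760.0


def pa_kpa(Ta, RH):
    return RH * psat_kpa(Ta)


def metabolic(vo2, rer, bsa_m2):
    kj = ((rer - 0.7) / 0.3) * 21.13 + ((1.0 - rer) / 0.3) * 19.62
    return vo2 * kj / 60.0 * 1000.0 / bsa_m2


def work(mass, v, incline, bsa_m2):
    return 9.81 * mass * v * incline / 100.0 / bsa_m2


def hc(v, pb=760.0):
    return 6.51 * v**0.391 * (pb / 760.0) ** 0.55


def hr(tsk, tr):
    return 4.0 * 0.95 * 5.67e-8 * 0.72 * ((tsk + tr) / 2.0 + 273.15) ** 3


def convective(tsk, ta, v, pb=760.0):
    return hc(v, pb) * (tsk - ta)


def radiative(tsk, tr):
    return hr(tsk, tr) * (tsk - tr)


def respiratory(M, ta, pa):
    return 0.001516 * M * (28.56 + 0.641 * pa - 0.885 * ta) + 0.00127 * M * (
        59.34 + 0.53 * ta - 11.63 * pa
    )


def ereq(hprod, c, r, resp):
    return hprod - (c + r + resp)


def emax(tsk, ta, rh, v, pb=760.0, re_cl=0.01, f_cl=1.0, wmax=1.0):
    he = hc(v, pb) * 16.5 * (760.0 / pb) ** 0.45
    return wmax * (psat_kpa(tsk) - pa_kpa(ta, rh)) / (re_cl + 1.0 / (he * f_cl))
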