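"""Orthogonal wavelet filter banks.

Decomposition low-pass filters for the ten mother wavelets supported by the
denoiser: Haar, Daubechies (2, 4, 6), Symlets (2, 4, 6) and Coiflets
(2, 4, 5) -- names follow the common ``db``/``sym``/``coif`` convention and
the order of each family equals its number of vanishing wavelet moments.

The constants were computed from first principles by
``scripts/make_filters.py`` (spectral factorization for the Daubechies and
least-asymmetric families; a Newton solve of the moment/orthonormality
equations for the Coiflets) and are exact solutions to ~1e-15.  The test
suite independently verifies unit norm, sum sqrt(2), double-shift
orthogonality and the vanishing-moment counts, so correctness does not rest
on trusting this table.
"""

import numpy as np

DEC_LO = {
    "haar": [
         7.07106781186547462e-01,  7.07106781186547462e-01,
    ],
    "db2": [
         4.82962913144534156e-01,  8.36516303737807831e-01,  2.24143868042013389e-01,
        -1.29409522551260370e-01,
    ],
    "db4": [
         2.30377813308896090e-01,  7.14846570552914673e-01,  6.30880767929858588e-01,
        -2.79837694168587788e-02, -1.87034811719092309e-01,  3.08413818355606703e-02,
         3.28830116668851063e-02, -1.05974017850689987e-02,
    ],
    "db6": [
         1.11540743350109245e-01,  4.94623890398452948e-01,  7.51133908021097918e-01,
         3.15250351709203569e-01, -2.26264693965436664e-01, -1.29766867567265659e-01,
         9.75016055873178661e-02,  2.75228655303038534e-02, -3.15820393174861686e-02,
         5.53842201161362769e-04,  4.77725751094545611e-03, -1.07730108530846398e-03,
    ],
    "sym2": [
        -1.29409522551260370e-01,  2.24143868042013389e-01,  8.36516303737807831e-01,
         4.82962913144534156e-01,
    ],
    "sym4": [
         3.22231006040514453e-02, -1.26039672620310867e-02, -9.92195435766330125e-02,
         2.97857795605305786e-01,  8.03738751805130991e-01,  4.97618667632774847e-01,
        -2.96355276460018476e-02, -7.57657147895019062e-02,
    ],
    "sym6": [
        -7.80070832503344976e-03,  1.76771186425075987e-03,  4.47249017707804300e-02,
        -2.10602925123707096e-02, -7.26375227863962081e-02,  3.37929421728129120e-01,
         7.87641141028646352e-01,  4.91055941928013884e-01, -4.83117425856642371e-02,
        -1.17990111148517887e-01,  3.49071208421471938e-03,  1.54041093270424791e-02,
    ],
    "coif2": [
        -7.20549445520359553e-04, -1.82320887091047806e-03,  5.61143481936781686e-03,
         2.36801719468461638e-02, -5.94344186464268870e-02, -7.64885990782798592e-02,
         4.17005184423232700e-01,  8.12723635449414950e-01,  3.86110066822767106e-01,
        -6.73725547237274680e-02, -4.14649367868728386e-02,  1.63873364632042481e-02,
    ],
    "coif4": [
        -1.78499091496179843e-06, -3.25964794180116722e-06,  3.12298616074627671e-05,
         6.23388543246347973e-05, -2.59974337152381048e-04, -5.89020224745293659e-04,
         1.26656107907335575e-03,  3.75143469774162673e-03, -5.65828380106548918e-03,
        -1.52117281892642404e-02,  2.50822533413670758e-02,  3.93344226076276435e-02,
        -9.62204245431729638e-02, -6.66274723675367581e-02,  4.34386033123782711e-01,
         7.82238934422679222e-01,  4.15308426992887281e-01, -5.60773196009489577e-02,
        -8.12667102451951895e-02,  2.66823046678145055e-02,  1.60689471304092599e-02,
        -7.34616793565299759e-03, -1.62949242507867058e-03,  8.92313902449991952e-04,
    ],
    "coif5": [
        -9.59984028675036552e-08, -1.62336922681112178e-07,  2.06069124089440073e-06,
         3.69952559454788695e-06, -2.12656860989201536e-05, -4.12112866711575923e-05,
         1.40337452030095167e-04,  3.01805039639440860e-04, -6.37490071278305412e-04,
        -1.66136155663909840e-03,  2.43122212086052973e-03,  6.76065917299552548e-03,
        -9.15800065914369223e-03, -1.97566988078966693e-02,  3.26706048922160083e-02,
         4.12856773929759086e-02, -1.05555444107289051e-01, -6.20372063375779076e-02,
         4.37972668713748403e-01,  7.74295103486727809e-01,  4.21579570632413525e-01,
        -5.20491752612244341e-02, -9.19264628186150096e-02,  2.81717233946018365e-02,
         2.34101909120178371e-02, -1.01324879613807380e-02, -4.15973557834982757e-03,
         2.17852391839958937e-03,  3.58620691197562109e-04, -2.12107196074816248e-04,
    ],
}


#: Number of vanishing wavelet moments per filter (order of the family).
VANISHING_MOMENTS = {
    "haar": 1, "db2": 2, "db4": 4, "db6": 6,
    "sym2": 2, "sym4": 4, "sym6": 6,
    "coif2": 4, "coif4": 8, "coif5": 10,
}

WAVELETS = tuple(DEC_LO)


def dec_lo(name):
    """Decomposition low-pass filter as a float64 array."""
    try:
        return np.asarray(DEC_LO[name], dtype=np.float64)
    except KeyError:
        raise ValueError(
            f"unknown wavelet {name!r}; supported: {', '.join(DEC_LO)}"
        ) from None


def dec_hi(name):
    """Decomposition high-pass filter via the quadrature-mirror relation."""
    h = dec_lo(name)
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return g
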