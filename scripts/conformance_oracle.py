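"""Brute-force oracle for the eight GFR estimating equations.

Writes tests/data/equation_conformance.csv. Deliberately written as flat,
repetitive arithmetic straight from the original equation publications
(CKD-EPI 2009/2012/2021, EKFC 2021/2023) so it shares no code with the
package implementation it is used to check.

Run from the repository root:  python scripts/conformance_oracle.py
"""
import csv
import pathlib

MGDL_PER_UMOL = 1.0 / 88.4


def ckdepi_cr_2009(scr_mgdl, age, female, black):
    k = 0.7 if female else 0.9
    a = -0.329 if female else -0.411
    r = scr_mgdl / k
    g = 141.0 * min(r, 1.0) ** a * max(r, 1.0) ** -1.209 * 0.993 ** age
    if female:
        g *= 1.018
    if black:
        g *= 1.159
    return g


def ckdepi_cys_2012(scys, age, female):
    r = scys / 0.8
    g = 133.0 * min(r, 1.0) ** -0.499 * max(r, 1.0) ** -1.328 * 0.996 ** age
    if female:
        g *= 0.932
    return g


def ckdepi_crcys_2012(scr_mgdl, scys, age, female, black):
    k = 0.7 if female else 0.9
    a = -0.248 if female else -0.207
    rc = scr_mgdl / k
    ry = scys / 0.8
    g = (135.0 * min(rc, 1.0) ** a * max(rc, 1.0) ** -0.601
         * min(ry, 1.0) ** -0.375 * max(ry, 1.0) ** -0.711 * 0.995 ** age)
    if female:
        g *= 0.969
    if black:
        g *= 1.08
    return g


def ckdepi_cr_2021(scr_mgdl, age, female):
    k = 0.7 if female else 0.9
    a = -0.241 if female else -0.302
    r = scr_mgdl / k
    g = 142.0 * min(r, 1.0) ** a * max(r, 1.0) ** -1.200 * 0.9938 ** age
    if female:
        g *= 1.012
    return g


def ckdepi_crcys_2021(scr_mgdl, scys, age, female):
    k = 0.7 if female else 0.9
    a = -0.219 if female else -0.144
    rc = scr_mgdl / k
    ry = scys / 0.8
    g = (135.0 * min(rc, 1.0) ** a * max(rc, 1.0) ** -0.544
         * min(ry, 1.0) ** -0.323 * max(ry, 1.0) ** -0.778 * 0.9961 ** age)
    if female:
        g *= 0.963
    return g


def ekfc_cr(scr_umol, age, female):
    q = 62.0 if female else 80.0
    r = scr_umol / q
    x = 0.322 if r < 1.0 else 1.132
    g = 107.3 / r ** x
    if age > 40:
        g *= 0.990 ** (age - 40)
    return g


def ekfc_cys(scys, age):
    q = 0.83 if age < 50 else 0.83 + 0.005 * (age - 50)
    r = scys / q
    x = 0.322 if r < 1.0 else 1.132
    g = 107.3 / r ** x
    if age > 40:
        g *= 0.990 ** (age - 40)
    return g


def ekfc_crcys(scr_umol, scys, age, female):
    return 0.5 * (ekfc_cr(scr_umol, age, female) + ekfc_cys(scys, age))


# (sex, age, creatinine µmol/L, cystatin mg/L) — spans both sides of the
# CKD-EPI knots (0.9/0.7 mg/dL cr, 0.8 mg/L cys) and the EKFC Q ratio 1.
PANELS = [
    ("male", 25, 61.88, 0.60),    # cr 0.70 mg/dL, below all male knots
    ("male", 50, 123.76, 1.50),   # cr 1.40 mg/dL, above knots
    ("male", 80, 84.0, 0.85),     # near the male knots from above
    ("female", 25, 63.65, 0.81),  # cr 0.72 mg/dL, just above female knot
    ("female", 50, 53.04, 0.70),  # cr 0.60 mg/dL, below knots
    ("female", 80, 221.0, 2.20),  # cr 2.50 mg/dL, severe reduction
]


def main():
    rows = []
    for sex, age, scr_umol, scys in PANELS:
        female = sex == "female"
        scr = scr_umol * MGDL_PER_UMOL
        vals = {
            "CKDEPI_CR_2009": ckdepi_cr_2009(scr, age, female, False),
            "CKDEPI_CYS_2012": ckdepi_cys_2012(scys, age, female),
            "CKDEPI_CRCYS_2012": ckdepi_crcys_2012(scr, scys, age, female, False),
            "CKDEPI_CR_2021": ckdepi_cr_2021(scr, age, female),
            "CKDEPI_CRCYS_2021": ckdepi_crcys_2021(scr, scys, age, female),
            "EKFC_CR": ekfc_cr(scr_umol, age, female),
            "EKFC_CYS": ekfc_cys(scys, age),
            "EKFC_CRCYS": ekfc_crcys(scr_umol, scys, age, female),
        }
        for eq, g in vals.items():
            rows.append([eq, sex, age, scr_umol, scys, "false", f"{g:.10f}"])
    # race-term path of the 2009/2012 equations
    rows.append(["CKDEPI_CR_2009", "male", 50, 123.76, 1.50, "true",
                 f"{ckdepi_cr_2009(123.76 * MGDL_PER_UMOL, 50, False, True):.10f}"])
    rows.append(["CKDEPI_CRCYS_2012", "female", 50, 53.04, 0.70, "true",
                 f"{ckdepi_crcys_2012(53.04 * MGDL_PER_UMOL, 0.70, 50, True, True):.10f}"])

    out = pathlib.Path(__file__).resolve().parents[1] / "tests" / "data" / "equation_conformance.csv"
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["equation", "sex", "age", "serum_creatinine_umol",
                    "serum_cystatin_c", "apply_race_term", "expected_gfr"])
        w.writerows(rows)
    print(f"wrote {len(rows)} rows -> {out}")


if __name__ == "__main__":
    main()
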