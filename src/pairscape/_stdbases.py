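"""Frozen standard deoxynucleotide coordinates in the base-fixed reference frame.

Each entry lists (atom_name, element, xyz) for one nucleotide (5'-phosphate
included; terminal OP3 omitted).  The base ring lies in the z = 0 plane with
the Watson-Crick edge facing +y... more precisely, the placement follows the
standard base reference-frame convention (minor-groove edge at -x, pairing
partner reached by a 180 deg flip about x), uniformly offset along y so that
an ideal pair built from two flipped copies shows canonical hydrogen-bond
heavy-atom distances of 2.7-2.9 A.  Sugar and backbone atoms are idealized
single-conformer coordinates rotated to an anti glycosidic torsion
(chi = -120 deg).  Derived once from idealized chemical-component geometries
and embedded as literals so the package carries no structural-database
dependency.
"""

STANDARD_NUCLEOTIDES = {
    "DA": [
        ("P", "P", (-2.5862, 9.4796, -4.0005)),
        ("OP1", "O", (-1.1074, 9.482, -4.0523)),
        ("OP2", "O", (-3.1057, 10.8889, -3.4217)),
        ("O5'", "O", (-3.0877, 8.2875, -3.0425)),
        ("C5'", "C", (-2.5359, 8.5368, -1.749)),
        ("C4'", "C", (-2.9763, 7.4341, -0.7845)),
        ("O4'", "O", (-2.411, 6.16, -1.1696)),
        ("C3'", "C", (-2.3918, 7.6794, 0.6293)),
        ("O3'", "O", (-3.2357, 8.548, 1.3877)),
        ("C2'", "C", (-2.3866, 6.2537, 1.2292)),
        ("C1'", "C", (-2.4304, 5.3265, -0.0002)),
        ("N9", "N", (-1.2612, 4.4429, 0.0002)),
        ("C8", "C", (0.0436, 4.833, -0.001)),
        ("N7", "N", (0.8198, 3.7887, -0.0015)),
        ("C5", "C", (0.0641, 2.6644, 0.005)),
        ("C6", "C", (0.3405, 1.2872, -0.0013)),
        ("N6", "N", (1.6457, 0.8271, -0.0025)),
        ("N1", "N", (-0.6803, 0.4361, -0.0006)),
        ("C2", "C", (-1.9276, 0.8659, -0.0003)),
        ("N3", "N", (-2.2349, 2.1454, -0.0)),
        ("C4", "C", (-1.281, 3.0714, -0.0006)),
        ("H5'", "H", (-2.8888, 9.5018, -1.384)),
        ("H5''", "H", (-1.4487, 8.5494, -1.8141)),
        ("H4'", "H", (-4.0633, 7.3729, -0.7449)),
        ("H3'", "H", (-1.3801, 8.0801, 0.567)),
        ("HO3'", "H", (-2.8685, 8.586, 2.2806)),
        ("H2'", "H", (-3.2638, 6.0997, 1.8564)),
        ("H2''", "H", (-1.4735, 6.0848, 1.8019)),
        ("H1'", "H", (-3.3438, 4.7317, 0.017)),
        ("H8", "H", (0.3838, 5.8576, -0.0011)),
        ("H61", "H", (1.8241, -0.1262, -0.0022)),
        ("H62", "H", (2.3826, 1.4587, -0.0064)),
        ("H2", "H", (-2.7272, 0.1397, -0.0007)),
    ],
    "DC": [
        ("P", "P", (-2.6758, 9.4379, -4.0047)),
        ("OP1", "O", (-1.1972, 9.4552, -4.0604)),
        ("OP2", "O", (-3.2079, 10.8417, -3.4262)),
        ("O5'", "O", (-3.1624, 8.2407, -3.0433)),
        ("C5'", "C", (-2.6099, 8.4987, -1.7526)),
        ("C4'", "C", (-3.0363, 7.393, -0.7848)),
        ("O4'", "O", (-2.4584, 6.1255, -1.1686)),
        ("C3'", "C", (-2.4508, 7.6463, 0.6271)),
        ("O3'", "O", (-3.3028, 8.5074, 1.3858)),
        ("C2'", "C", (-2.4281, 6.222, 1.2298)),
        ("C1'", "C", (-2.4653, 5.2918, 0.0015)),
        ("N1", "N", (-1.2877, 4.4209, 0.0002)),
        ("C2", "C", (-1.4436, 3.0856, 0.0007)),
        ("O2", "O", (-2.5684, 2.6127, 0.0027)),
        ("N3", "N", (-0.3901, 2.2704, -0.0001)),
        ("C4", "C", (0.8432, 2.7571, -0.0014)),
        ("N4", "N", (1.9239, 1.9059, -0.0015)),
        ("C5", "C", (1.0402, 4.1529, 0.0022)),
        ("C6", "C", (-0.04, 4.9682, -0.0017)),
        ("H5'", "H", (-2.9722, 9.4598, -1.3874)),
        ("H5''", "H", (-1.5227, 8.5223, -1.8188)),
        ("H4'", "H", (-4.1229, 7.3201, -0.7421)),
        ("H3'", "H", (-1.444, 8.0578, 0.5624)),
        ("HO3'", "H", (-2.9325, 8.55, 2.2786)),
        ("H2'", "H", (-3.3028, 6.0598, 1.8587)),
        ("H2''", "H", (-1.5124, 6.0628, 1.8003)),
        ("H1'", "H", (-3.3728, 4.6884, 0.0216)),
        ("H41", "H", (1.7844, 0.9461, -0.0005)),
        ("H42", "H", (2.8248, 2.2653, -0.0071)),
        ("H5", "H", (2.0389, 4.5659, 0.0008)),
        ("H6", "H", (0.0858, 6.0404, -0.0033)),
    ],
    "DG": [
        ("P", "P", (-2.5883, 9.5482, -4.0)),
        ("OP1", "O", (-1.11, 9.5499, -4.0537)),
        ("OP2", "O", (-3.1065, 10.9564, -3.4218)),
        ("O5'", "O", (-3.0898, 8.3561, -3.0413)),
        ("C5'", "C", (-2.5367, 8.6063, -1.7486)),
        ("C4'", "C", (-2.9765, 7.5041, -0.7834)),
        ("O4'", "O", (-2.412, 6.2298, -1.1682)),
        ("C3'", "C", (-2.3901, 7.7493, 0.6303)),
        ("O3'", "O", (-3.2337, 8.6192, 1.3888)),
        ("C2'", "C", (-2.3842, 6.3234, 1.2306)),
        ("C1'", "C", (-2.4288, 5.3958, 0.0015)),
        ("N9", "N", (-1.2618, 4.5119, 0.0006)),
        ("C8", "C", (0.0451, 4.9022, 0.0009)),
        ("N7", "N", (0.8187, 3.8554, -0.0002)),
        ("C5", "C", (0.0564, 2.7347, -0.0011)),
        ("C6", "C", (0.3415, 1.3492, -0.0024)),
        ("O6", "O", (1.4927, 0.9489, -0.003)),
        ("N1", "N", (-0.6938, 0.4818, 0.0042)),
        ("C2", "C", (-1.9764, 0.9402, -0.0013)),
        ("N2", "N", (-3.0076, 0.0355, -0.0023)),
        ("N3", "N", (-2.2543, 2.2246, -0.0014)),
        ("C4", "C", (-1.2824, 3.1439, 0.0006)),
        ("H5'", "H", (-2.8887, 9.5707, -1.384)),
        ("H5''", "H", (-1.4486, 8.6177, -1.8141)),
        ("H4'", "H", (-4.0636, 7.4427, -0.742)),
        ("H3'", "H", (-1.3781, 8.1495, 0.5676)),
        ("HO3'", "H", (-2.865, 8.6562, 2.2814)),
        ("H2'", "H", (-3.2623, 6.1695, 1.8576)),
        ("H2''", "H", (-1.4713, 6.1548, 1.8017)),
        ("H1'", "H", (-3.3431, 4.8019, 0.0199)),
        ("H8", "H", (0.3875, 5.9271, 0.0014)),
        ("H1", "H", (-0.5224, -0.4733, 0.003)),
        ("H21", "H", (-3.9261, 0.3469, -0.002)),
        ("H22", "H", (-2.8184, -0.916, -0.0073)),
    ],
    "DT": [
        ("P", "P", (0.5292, 8.9131, -2.7468)),
        ("OP1", "O", (0.8609, 8.8224, -4.2077)),
        ("OP2", "O", (0.359, 10.4159, -2.1764)),
        ("O5'", "O", (-0.8603, 8.2035, -2.3158)),
        ("C5'", "C", (-1.2447, 8.244, -0.9518)),
        ("C4'", "C", (-2.5739, 7.5179, -0.7931)),
        ("O4'", "O", (-2.3743, 6.142, -1.1717)),
        ("C3'", "C", (-3.0696, 7.4959, 0.6459)),
        ("O3'", "O", (-4.4899, 7.372, 0.6684)),
        ("C2'", "C", (-2.4393, 6.242, 1.2061)),
        ("C1'", "C", (-2.4219, 5.317, 0.0002)),
        ("N1", "N", (-1.298, 4.4261, -0.0002)),
        ("C2", "C", (-1.474, 3.0258, 0.0)),
        ("O2", "O", (-2.5755, 2.4729, -0.0003)),
        ("N3", "N", (-0.2907, 2.2802, 0.0003)),
        ("C4", "C", (1.0056, 2.7727, -0.0004)),
        ("O4", "O", (2.0041, 2.058, -0.0014)),
        ("C5", "C", (1.1103, 4.2562, 0.0003)),
        ("C7", "C", (2.4756, 4.8652, 0.0007)),
        ("C6", "C", (-0.0212, 4.973, -0.0)),
        ("H5'", "H", (-0.4728, 7.7589, -0.3503)),
        ("H5''", "H", (-1.3427, 9.2873, -0.6416)),
        ("H4'", "H", (-3.3101, 7.951, -1.4774)),
        ("H3'", "H", (-2.8117, 8.3969, 1.2096)),
        ("HO3'", "H", (-4.8337, 8.0853, 1.234)),
        ("H2'", "H", (-1.4176, 6.459, 1.5404)),
        ("H2''", "H", (-2.9888, 5.8027, 2.0446)),
        ("H1'", "H", (-3.3309, 4.708, -0.0518)),
        ("H3", "H", (-0.3929, 1.2696, -0.0)),
        ("H71", "H", (3.017, 4.5515, 0.8917)),
        ("H72", "H", (2.3948, 5.9517, -0.0089)),
        ("H73", "H", (3.0215, 4.5442, -0.8861)),
        ("H6", "H", (0.0107, 6.0586, 0.0001)),
    ],
}
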