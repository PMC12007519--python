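{
  "_comment": "Proton spin systems for brain metabolites: chemical shifts (ppm, one entry per proton) and scalar couplings (Hz) as sparse [i, j, J] triples. Values follow standard literature compilations of brain-metabolite NMR parameters; this table is editable configuration.",
  "NAA": {
    "shifts": [2.008, 2.008, 2.008, 4.382, 2.6727, 2.4863],
    "j": [[3, 4, 3.861], [3, 5, 9.821], [4, 5, -15.592]]
  },
  "NAAG": {
    "shifts": [2.042, 2.042, 2.042, 4.607, 2.721, 2.519],
    "j": [[3, 4, 4.412], [3, 5, 9.52], [4, 5, -15.91]]
  },
  "Cr": {
    "shifts": [3.027, 3.027, 3.027, 3.913, 3.913],
    "j": []
  },
  "PCr": {
    "shifts": [3.029, 3.029, 3.029, 3.93, 3.93],
    "j": []
  },
  "GPC": {
    "shifts": [3.212, 3.212, 3.212, 3.212, 3.212, 3.212, 3.212, 3.212, 3.212, 3.605, 3.672, 4.312, 4.312],
    "j": [[9, 10, -9.32], [9, 11, 3.1], [10, 11, 5.9]]
  },
  "PCho": {
    "shifts": [3.208, 3.208, 3.208, 3.208, 3.208, 3.208, 3.208, 3.208, 3.208, 4.282, 4.282, 3.641, 3.641],
    "j": [[9, 11, 3.14], [9, 12, 6.03], [10, 11, 6.03], [10, 12, 3.14]]
  },
  "mI": {
    "shifts": [3.522, 4.054, 3.522, 3.614, 3.269, 3.614],
    "j": [[0, 1, 2.889], [1, 2, 3.006], [2, 3, 9.997], [3, 4, 9.485], [4, 5, 9.482], [0, 5, 9.998]]
  },
  "sI": {
    "shifts": [3.34, 3.34, 3.34, 3.34, 3.34, 3.34],
    "j": []
  },
  "Glu": {
    "shifts": [3.7433, 2.0375, 2.12, 2.3378, 2.352],
    "j": [[0, 1, 7.331], [0, 2, 4.651], [1, 2, -14.849], [1, 3, 6.413], [1, 4, 8.406], [2, 3, 8.478], [2, 4, 6.875], [3, 4, -15.915]]
  },
  "Gln": {
    "shifts": [3.753, 2.129, 2.109, 2.432, 2.454],
    "j": [[0, 1, 5.847], [0, 2, 6.5], [1, 2, -14.45], [1, 3, 9.16], [1, 4, 6.35], [2, 3, 6.33], [2, 4, 9.25], [3, 4, -15.55]]
  },
  "GSH": {
    "shifts": [3.769, 3.769, 4.5608, 2.9264, 2.9747, 3.769, 2.159, 2.146, 2.51, 2.56],
    "j": [[2, 3, 7.09], [2, 4, 4.71], [3, 4, -14.06], [5, 6, 6.34], [5, 7, 6.36], [6, 7, -15.48], [6, 8, 6.7], [6, 9, 7.6], [7, 8, 7.6], [7, 9, 6.7], [8, 9, -15.92]]
  },
  "GABA_1": {
    "shifts": [2.284, 2.284, 1.889, 1.889, 3.0128, 3.0128],
    "j": [[0, 2, 7.755], [0, 3, 7.432], [1, 2, 6.173], [1, 3, 7.933], [2, 4, 5.372], [2, 5, 10.578], [3, 4, 7.127], [3, 5, 6.982]]
  },
  "GABA_2": {
    "shifts": [2.2966, 2.2966, 1.9095, 1.9095, 3.0115, 3.0115],
    "j": [[0, 2, 7.3], [0, 3, 7.3], [1, 2, 7.3], [1, 3, 7.3], [2, 4, 7.1], [2, 5, 7.1], [3, 4, 7.1], [3, 5, 7.1]]
  },
  "Glc_A": {
    "shifts": [5.216, 3.519, 3.698, 3.395, 3.822, 3.826, 3.749],
    "j": [[0, 1, 3.8], [1, 2, 9.6], [2, 3, 9.4], [3, 4, 9.9], [4, 5, 1.5], [4, 6, 6.0], [5, 6, -12.1]]
  },
  "Glc_B": {
    "shifts": [4.63, 3.23, 3.473, 3.387, 3.45, 3.882, 3.707],
    "j": [[0, 1, 8.0], [1, 2, 9.1], [2, 3, 9.4], [3, 4, 8.9], [4, 5, 1.6], [4, 6, 5.4], [5, 6, -12.3]]
  },
  "Lac": {
    "shifts": [1.3142, 1.3142, 1.3142, 4.0974],
    "j": [[0, 3, 6.933], [1, 3, 6.933], [2, 3, 6.933]]
  },
  "Asp": {
    "shifts": [3.8914, 2.8011, 2.6533],
    "j": [[0, 1, 3.647], [0, 2, 9.107], [1, 2, -17.426]]
  },
  "Asc": {
    "shifts": [4.49, 4.0, 3.74, 3.72],
    "j": [[0, 1, 2.07], [1, 2, 5.6], [1, 3, 7.0], [2, 3, -11.5]]
  },
  "Tau": {
    "shifts": [3.4206, 3.4206, 3.2459, 3.2459],
    "j": [[0, 2, 6.742], [0, 3, 6.403], [1, 2, 6.403], [1, 3, 6.742]]
  },
  "PE": {
    "shifts": [3.9765, 3.9765, 3.2164, 3.2164],
    "j": [[0, 2, 3.18], [0, 3, 6.72], [1, 2, 6.72], [1, 3, 3.18]]
  },
  "Ser": {
    "shifts": [3.8347, 3.9379, 3.9764],
    "j": [[0, 1, 5.979], [0, 2, 3.561], [1, 2, -12.254]]
  },
  "Gly": {
    "shifts": [3.548, 3.548],
    "j": []
  },
  "Ala": {
    "shifts": [1.4667, 1.4667, 1.4667, 3.7746],
    "j": [[0, 3, 7.234], [1, 3, 7.234], [2, 3, 7.234]]
  },
  "Thr": {
    "shifts": [1.3157, 1.3157, 1.3157, 4.2464, 3.5785],
    "j": [[0, 3, 6.35], [1, 3, 6.35], [2, 3, 6.35], [3, 4, 4.92]]
  }
}
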