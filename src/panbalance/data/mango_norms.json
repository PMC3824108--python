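{
  "description": "Reference nutrient-balance norms for mango (Mangifera indica) foliar ionomes: median ilr balances, their 95% confidence limits and covariance matrix of the 20 true-negative (balanced, high-yielding) orchards from a 175-orchard Brazilian survey, with the calibrated critical Mahalanobis distance and yield cut-off.",
  "balance_names": [
    "[Fv | S,N,P,K,Ca,Mg,B,Cu,Zn,Mn,Fe]",
    "[Cu,Zn,Mn,Fe | S,N,P,K,Ca,Mg,B]",
    "[B | S,N,P,K,Ca,Mg]",
    "[K,Ca,Mg | S,N,P]",
    "[P | S,N]",
    "[N | S]",
    "[Ca,Mg | K]",
    "[Mg | Ca]",
    "[Fe | Cu,Zn,Mn]",
    "[Mn | Cu,Zn]",
    "[Zn | Cu]"
  ],
  "center": [-7.086, 5.518, 4.639, -1.205, 1.300, -1.628, 0.345, 1.598, -0.005, -2.374, 0.218],
  "ci_lower": [-7.153, 5.394, 4.454, -1.312, 1.227, -1.652, 0.248, 1.563, -0.162, -2.554, -0.148],
  "ci_upper": [-7.000, 5.859, 4.720, -1.170, 1.338, -1.551, 0.407, 1.682, 0.095, -2.131, 0.539],
  "covariance": [
    [0.0267, -0.0653, -0.0289, 0.0158, 0.0068, 0.0076, 0.0053, -0.0032, 0.0203, 0.0507, 0.0619],
    [-0.0653, 0.2467, 0.0403, -0.0299, -0.0344, -0.0233, 0.0076, 0.0003, -0.0612, -0.1155, -0.2338],
    [-0.0289, 0.0403, 0.0808, -0.0173, 0.0024, -0.0025, 0.0000, 0.0132, -0.0388, -0.0809, -0.0614],
    [0.0158, -0.0299, -0.0173, 0.0233, -0.0008, 0.0009, 0.0109, -0.0082, 0.0196, 0.0330, 0.0111],
    [0.0068, -0.0344, 0.0024, -0.0008, 0.0140, -0.0003, -0.0092, 0.0024, 0.0056, -0.0048, 0.0423],
    [0.0076, -0.0233, -0.0025, 0.0009, -0.0003, 0.0117, 0.0038, 0.0039, 0.0024, 0.0266, 0.0156],
    [0.0053, 0.0076, 0.0000, 0.0109, -0.0092, 0.0038, 0.0288, -0.0039, 0.0003, 0.0219, -0.0330],
    [-0.0032, 0.0003, 0.0132, -0.0082, 0.0024, 0.0039, -0.0039, 0.0161, -0.0106, -0.0091, -0.0254],
    [0.0203, -0.0612, -0.0388, 0.0196, 0.0056, 0.0024, 0.0003, -0.0106, 0.0757, 0.0617, 0.0626],
    [0.0507, -0.1155, -0.0809, 0.0330, -0.0048, 0.0266, 0.0219, -0.0091, 0.0617, 0.2040, 0.1599],
    [0.0619, -0.2338, -0.0614, 0.0111, 0.0423, 0.0156, -0.0330, -0.0254, 0.0626, 0.1599, 0.5378]
  ],
  "critical_distance": 4.08,
  "yield_cutoff": 128.5,
  "n_ref": 20
}
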