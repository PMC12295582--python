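{
  "description": "Monk Skin Tone scale reference swatches, RGB triples from the published 10-color palette (hex f6ede4, f3e7db, f7ead0, eadaba, d7bd96, a07e56, 825c43, 604134, 3a312a, 292420). Editable: replace with swatch pixel samples if richer references are available.",
  "scales": [
    {"id": 1, "rgbs": [[246, 237, 228]]},
    {"id": 2, "rgbs": [[243, 231, 219]]},
    {"id": 3, "rgbs": [[247, 234, 208]]},
    {"id": 4, "rgbs": [[234, 218, 186]]},
    {"id": 5, "rgbs": [[215, 189, 150]]},
    {"id": 6, "rgbs": [[160, 126, 86]]},
    {"id": 7, "rgbs": [[130, 92, 67]]},
    {"id": 8, "rgbs": [[96, 65, 52]]},
    {"id": 9, "rgbs": [[58, 49, 42]]},
    {"id": 10, "rgbs": [[41, 36, 32]]}
  ]
}
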