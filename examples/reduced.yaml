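# Reduced-width configuration for quick CPU runs (same architecture,
# d=64 instead of 256, 2 interfusion blocks instead of 6).
encoder:
  atom_embed_dim: 64
  gat_heads: 4
  gat_head_dim: 16
interfusion:
  d: 64
  d_k: 16
  heads: 4
  n_blocks: 2
  ffn_hidden: 256
training:
  batch_size: 1000
  epochs: 25
  lr: 0.001
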