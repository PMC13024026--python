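"""Trace the shapes and token counts of the full model on a standard input.

Prints the stage-by-stage feature-map shapes of the CoTResNet3D backbone and
the token counts / positional-encoding axis splits of the two CrossViT
streams, computed from layer arithmetic alone.  On the standard 84x102x84
gray-matter density input the backbone emits 64x21x26x21, 128x11x13x11 and
256x6x7x6 maps; 2x2x2 patching then yields 150 large-stream and 27
small-stream tokens.
"""

from brainage import inspect_shapes, build_model

info = inspect_shapes((84, 102, 84))
print("input volume: 84 x 102 x 84 (single channel)")
for stage, shape in info["stage_shapes"].items():
    print(f"  {stage}: {shape[0]} channels, {shape[1]}x{shape[2]}x{shape[3]}")
for name in ("small_stream", "large_stream"):
    s = info[name]
    print(f"  {name}: {s['patches']} patch tokens (+1 cls), embed dim "
          f"{s['embed_dim']}, PE axis split {s['axis_split']}")

model = build_model(seed=0)
print(f"assembled ResNet-CrossViT parameters: {model.num_parameters():,}")
print("(the two streams exchange information through gated bidirectional "
      "cross-attention between each stream's cls token and the other's patches)")
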