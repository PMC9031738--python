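"""Transfer communicator labels across input sizes (224 crops -> 299 tiles).

A 299-native backbone (the inception-style input size) cannot be fed the
224 px tiles the communicators were built on.  Instead, each 299 tile is
center-cropped to 224 (offset 37 on both axes), the crop is classified,
and the label propagates back to the 299 parent — which then serves as
training data for the 299-native head.
"""

from tilepurify.experiments import cross_size_transfer_experiment

out = cross_size_transfer_experiment(seed=7)
print(f"299 px parent tiles: {out.n_parents}")
print(f"labeled via their 224 px center crops: {out.n_labeled} "
      f"(bookkeeping loss: {out.transfer_loss})")
print(f"299-native backbone validation accuracy on transferred labels: "
      f"{out.inception_val_accuracy:.1%}")
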