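"""The step-decay learning-rate schedule and the evaluation metrics.

First prints the "8-5 gradient" schedule lr_n = 0.01 * 0.85^floor((n-1)/4):
piecewise constant, decaying every 4 epochs, 25 plateaus over 100 epochs.
Then evaluates a worked confusion-matrix example: of 100 samples, class 1
has TP=50, FP=10, FN=5, TN=35, giving accuracy 0.85, precision 0.833,
recall 0.909 and F1 0.870 (the harmonic mean of the two).
"""

import numpy as np

from hpfasternet import ConfusionMatrix, lr_at_epoch, metrics

lrs = [lr_at_epoch(n) for n in range(1, 101)]
print("epoch  1-4 :", lrs[0])
print("epoch  5-8 :", lrs[4])
print("epoch 13-16:", lrs[12])
print("epoch 97-100:", round(lrs[-1], 8))
print("distinct plateaus over 100 epochs:", len(set(lrs)))

cm = ConfusionMatrix(np.array([[35, 10],
                               [5, 50]]))
rep = metrics(cm)
tp, fp, fn, tn = cm.one_vs_rest(1)
print(f"\nclass 1 one-vs-rest counts: TP={tp} FP={fp} FN={fn} TN={tn}")
print(f"accuracy={rep.accuracy[1]:.4f} precision={rep.precision[1]:.4f} "
      f"recall={rep.recall[1]:.4f} F1={rep.f1[1]:.4f}")
print(f"macro over both classes: P={rep.macro['precision']:.4f} "
      f"R={rep.macro['recall']:.4f} F1={rep.macro['f1']:.4f}")
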