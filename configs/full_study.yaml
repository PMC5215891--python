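# Full-scale study configuration: the 279-neuron somatic connectome with
# 1,447 random distributed injuries.
#
# This run needs the connectome tables (not bundled here; see README for the
# expected layout).  Place under `data/connectome/`:
#   gap.csv       dense or (pre,post,count) gap-junction counts N^g
#   syn.csv       dense or (pre,post,count) chemical-synapse counts N^s
#                 (rows = postsynaptic, columns = presynaptic in the dense
#                 dialect)
#   polarity.csv  columns: neuron, polarity (excitatory|inhibitory), class
#   groups.json   {"input": ["PLML", "PLMR"],
#                  "motor": [... all DB, VB, DD, VD neurons ...]}
# and an empirically derived swelling histogram (value, probability) at
# `data/swelling_histogram.csv`.
#
# Run:  fasworm ensemble --config configs/full_study.yaml
# Expect hours of compute on one CPU (1,447 injuries x ~30 classification
# simulations each, 10^-4 s timestep).
connectome: data/connectome
histogram: data/swelling_histogram.csv
K: 1447
seed: 1
out_dir: results/full_study

input_current: 20000.0     # constant drive to the PLM pair, arb. units
input_group: input
record_group: motor        # forward-motion motorneurons: DB, VB, DD, VD
stride: 100                # 1 ms recording at dt = 1e-4 s
transient: 5.0
plane_duration: 20.0
classify_duration: 15.0
max_time: 60.0
radius: 0.01               # fixed-point confinement radius on the plane
rel_tol: 0.001             # mu* bisection bracket tolerance

n_shape_points: 200
min_leaf: 40               # minimum leaf size selected by the CV sweep
folds: 10
shuffle_trials: 100
feature_grid: 25
threshold: -0.01           # upper/lower split on leading-axis projections
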