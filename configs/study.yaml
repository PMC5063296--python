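master_seed: 1
truth_voxel_mm: 2.0
grid: 128
noise_scale: 120.0
n_levels: 64
volume_scanners:
- A
- C
- E
volume_acq_time_s: 120.0
cylinder_diameter_mm: 200.0
cylinder_length_mm: 200.0
cylinder_activity_kbq_ml: 5.0
voi_volumes_ml:
- 0.5
- 0.6776589899961868
- 0.9184434134453039
- 1.2447828718479896
- 1.687076607402123
- 2.286525259636632
- 3.0989687960922576
- 4.200088128779157
- 5.692454958486914
- 7.715086555534057
- 10.456395525912734
- 14.171740862181336
- 19.207215198306994
- 26.031884103848256
- 35.28148057902319
- 47.81762498950186
- 64.80808690880451
- 87.83556543641114
- 119.04512111876474
- 161.34399308263156
- 218.67241478865574
- 296.3706554914154
- 401.6764781296405
- 544.3993529491153
- 737.8342313481503
- 1000.0
settings:
- A
- B
- C
- D
- E
- F
acq_times_s:
- 60.0
- 120.0
- 180.0
- 240.0
n_replicates: 3
background_kbq_ml: 5.0
syringe_activities:
- 80.0
- 40.0
- 40.0
- 20.0
- 20.0
- 20.0
- 5.0
seg_threshold: 2.5
c11_activity_kbq_ml: 80.0
f18_activity_kbq_ml: 40.0
c11_syringes:
- 0
- 1
- 2
- 3
frame_cycle_min: 4.0
n_frames: 20
frame_acq_time_s: 120.0
dynamic_setting: B
v_min_ml: 30.0
slope_tol: 0.065
r2_min: 0.8
scatter_tol: 0.015
cv_max: 0.1
cell_pass_fraction: 0.75
s_min: 0.2
outdir: null
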