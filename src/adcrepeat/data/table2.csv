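patient_id,avg_voxels,delta_vol_pct,avg_mean_adc,delta_adc_pct,lesion_note,motion_flag
1,1141,0.44,76,18.56,,1
2,3214,8.47,102,-22.37,Sub-phrenic,1
3,2845,0.21,97,1.17,5% cystic,0
4,1297,0.15,77,14.69,,0
5,603,4.81,98,-3.39,Sub-phrenic,1
6,573,2.44,87,-2.52,,0
7,148,-14.63,123,2.25,,0
8,3178,-1.48,102,7.60,Sub-phrenic,1
9,4589,1.44,95,-4.35,,0
10,3731,28.19,103,1.69,,0
11,5957,0.32,140,6.48,,0
12,74572,-6.04,102,-12.13,,1
13,6780,-4.09,93,1.22,,0
14,270,-5.57,93,-7.36,,0
15,61130,-5.01,118,-1.11,,0
16,8788,4.79,127,-5.30,10% cystic,0
17,4315,-4.82,98,1.06,,0
18,2140,-2.38,129,1.04,,0
19,7914,8.38,198,2.84,95% cystic,0
20,4304,-3.53,110,-0.31,,0
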