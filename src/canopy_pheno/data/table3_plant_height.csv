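date,variety,group,plant_no,manual_cm,system_cm
2020-08-14,AD268,2500,1,47.3,47.96
2020-08-14,AD268,2500,2,45.9,46.1
2020-08-14,AD268,2500,3,47.8,48.13
2020-08-14,AD268,2500,4,51.4,51.71
2020-08-14,AD268,2500,5,46.2,48.56
2020-08-14,AD268,4000,1,52.6,53.49
2020-08-14,AD268,4000,2,52.3,53.47
2020-08-14,AD268,4000,3,49.7,50.27
2020-08-14,AD268,4000,4,50.1,51.29
2020-08-14,AD268,4000,5,48.9,49.57
2020-08-14,AD268,5500,1,52.2,53.26
2020-08-14,AD268,5500,2,50.6,50.79
2020-08-14,AD268,5500,3,53.3,51.91
2020-08-14,AD268,5500,4,54.5,53.6
2020-08-14,AD268,5500,5,55.4,54.98
2020-08-27,AD268,2500,1,76.3,78.48
2020-08-27,AD268,2500,2,79.5,82.24
2020-08-27,AD268,2500,3,80.3,77.79
2020-08-27,AD268,2500,4,84.1,83.15
2020-08-27,AD268,2500,5,83.5,85.81
2020-08-27,AD268,4000,1,79.2,78.64
2020-08-27,AD268,4000,2,82.6,83.41
2020-08-27,AD268,4000,3,83.1,84.19
2020-08-27,AD268,4000,4,86.4,88.41
2020-08-27,AD268,4000,5,81.7,79.76
2020-08-27,AD268,5500,1,87.9,88.83
2020-08-27,AD268,5500,2,91.4,90.6
2020-08-27,AD268,5500,3,91.4,88.51
2020-08-27,AD268,5500,4,90.6,92.43
2020-08-27,AD268,5500,5,92.3,91.46
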