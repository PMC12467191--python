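measure_name,location_name,cause_name,metric_name,age_name,year,val,upper,lower
Deaths,Global,Neoplasms,Rate,Age-standardized,1990,148.24,154.39,140.18
Deaths,High SDI,Neoplasms,Rate,Age-standardized,1990,170.96,175.00,162.88
Deaths,High-middle SDI,Neoplasms,Rate,Age-standardized,1990,173.65,182.46,163.76
Deaths,Middle SDI,Neoplasms,Rate,Age-standardized,1990,135.62,146.36,125.17
Deaths,Low-middle SDI,Neoplasms,Rate,Age-standardized,1990,82.45,88.04,75.29
Deaths,Low SDI,Neoplasms,Rate,Age-standardized,1990,98.74,110.68,87.84
Deaths,Global,Neoplasms,Rate,Age-standardized,2021,116.49,124.69,107.28
Deaths,High SDI,Neoplasms,Rate,Age-standardized,2021,123.22,128.96,113.06
Deaths,High-middle SDI,Neoplasms,Rate,Age-standardized,2021,134.01,147.09,121.72
Deaths,Middle SDI,Neoplasms,Rate,Age-standardized,2021,109.59,121.22,99.35
Deaths,Low-middle SDI,Neoplasms,Rate,Age-standardized,2021,85.03,90.89,79.17
Deaths,Low SDI,Neoplasms,Rate,Age-standardized,2021,90.64,102.00,79.86
DALYs (Disability-Adjusted Life Years),Global,Neoplasms,Rate,Age-standardized,1990,3969.21,4135.06,3792.05
DALYs (Disability-Adjusted Life Years),High SDI,Neoplasms,Rate,Age-standardized,1990,4341.14,4430.83,4215.00
DALYs (Disability-Adjusted Life Years),High-middle SDI,Neoplasms,Rate,Age-standardized,1990,4809.50,5055.08,4539.00
DALYs (Disability-Adjusted Life Years),Middle SDI,Neoplasms,Rate,Age-standardized,1990,3778.75,4077.32,3482.10
DALYs (Disability-Adjusted Life Years),Low-middle SDI,Neoplasms,Rate,Age-standardized,1990,2408.70,2562.93,2227.63
DALYs (Disability-Adjusted Life Years),Low SDI,Neoplasms,Rate,Age-standardized,1990,2864.53,3184.28,2554.22
DALYs (Disability-Adjusted Life Years),Global,Neoplasms,Rate,Age-standardized,2021,2953.59,3154.03,2769.24
DALYs (Disability-Adjusted Life Years),High SDI,Neoplasms,Rate,Age-standardized,2021,2920.60,3031.34,2751.48
DALYs (Disability-Adjusted Life Years),High-middle SDI,Neoplasms,Rate,Age-standardized,2021,3388.27,3728.81,3078.37
DALYs (Disability-Adjusted Life Years),Middle SDI,Neoplasms,Rate,Age-standardized,2021,2852.23,3158.67,2611.28
DALYs (Disability-Adjusted Life Years),Low-middle SDI,Neoplasms,Rate,Age-standardized,2021,2376.66,2542.90,2202.92
DALYs (Disability-Adjusted Life Years),Low SDI,Neoplasms,Rate,Age-standardized,2021,2487.39,2827.72,2164.52
Deaths,Global,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,71.92,77.53,64.47
Deaths,High SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,25.53,26.50,23.71
Deaths,High-middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,79.53,86.61,70.61
Deaths,Middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,123.89,134.80,109.19
Deaths,Low-middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,92.07,107.46,74.17
Deaths,Low SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,77.67,91.44,61.91
Deaths,Global,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,45.22,49.70,40.61
Deaths,High SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,19.44,20.66,17.26
Deaths,High-middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,35.91,40.69,30.78
Deaths,Middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,57.45,65.43,49.59
Deaths,Low-middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,84.76,93.78,75.80
Deaths,Low SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,70.70,79.76,63.35
DALYs (Disability-Adjusted Life Years),Global,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,1492.64,1609.30,1342.46
DALYs (Disability-Adjusted Life Years),High SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,589.80,616.39,557.84
DALYs (Disability-Adjusted Life Years),High-middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,1511.32,1635.67,1365.74
DALYs (Disability-Adjusted Life Years),Middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,2332.91,2546.31,2063.49
DALYs (Disability-Adjusted Life Years),Low-middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,1963.19,2252.75,1602.24
DALYs (Disability-Adjusted Life Years),Low SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,1990,1673.81,1936.99,1373.37
DALYs (Disability-Adjusted Life Years),Global,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,940.66,1014.59,871.48
DALYs (Disability-Adjusted Life Years),High SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,471.22,498.84,437.45
DALYs (Disability-Adjusted Life Years),High-middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,691.14,772.74,621.83
DALYs (Disability-Adjusted Life Years),Middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,1076.67,1201.24,963.62
DALYs (Disability-Adjusted Life Years),Low-middle SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,1707.90,1865.11,1558.88
DALYs (Disability-Adjusted Life Years),Low SDI,Chronic obstructive pulmonary disease,Rate,Age-standardized,2021,1457.94,1617.05,1318.76
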