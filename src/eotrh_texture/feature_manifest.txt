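fos_mean
fos_median
fos_minimum
fos_maximum
fos_percentile_10
fos_percentile_90
fos_variance
fos_root_mean_squared
fos_kurtosis
fos_skewness
fos_uniformity
fos_range
fos_interquartile_range
fos_mean_absolute_deviation
fos_robust_mean_absolute_deviation
fos_energy
fos_total_energy
fos_entropy
glcm_autocorrelation
glcm_cluster_prominence
glcm_cluster_shade
glcm_cluster_tendency
glcm_contrast
glcm_correlation
glcm_difference_average
glcm_difference_entropy
glcm_difference_variance
glcm_inverse_difference
glcm_inverse_difference_moment
glcm_inverse_difference_moment_normalized
glcm_inverse_difference_normalized
glcm_imc1
glcm_imc2
glcm_inverse_variance
glcm_joint_average
glcm_joint_energy
glcm_joint_entropy
glcm_maximal_correlation_coefficient
glcm_maximum_probability
glcm_sum_average
glcm_sum_entropy
glcm_sum_of_squares
ngtdm_busyness
ngtdm_coarseness
ngtdm_complexity
ngtdm_contrast
ngtdm_strength
gldm_dependence_entropy
gldm_dependence_non_uniformity
gldm_dependence_non_uniformity_normalized
gldm_dependence_variance
gldm_gray_level_non_uniformity
gldm_gray_level_variance
gldm_high_gray_level_emphasis
gldm_large_dependence_emphasis
gldm_large_dependence_high_gray_level_emphasis
gldm_large_dependence_low_gray_level_emphasis
gldm_low_gray_level_emphasis
gldm_small_dependence_emphasis
gldm_small_dependence_high_gray_level_emphasis
gldm_small_dependence_low_gray_level_emphasis
glrlm_gray_level_non_uniformity
glrlm_gray_level_non_uniformity_normalized
glrlm_gray_level_variance
glrlm_high_gray_level_run_emphasis
glrlm_long_run_emphasis
glrlm_long_run_high_gray_level_emphasis
glrlm_long_run_low_gray_level_emphasis
glrlm_low_gray_level_run_emphasis
glrlm_run_entropy
glrlm_run_length_non_uniformity
glrlm_run_length_non_uniformity_normalized
glrlm_run_percentage
glrlm_run_variance
glrlm_short_run_emphasis
glrlm_short_run_high_gray_level_emphasis
glrlm_short_run_low_gray_level_emphasis
glszm_gray_level_non_uniformity
glszm_gray_level_non_uniformity_normalized
glszm_gray_level_variance
glszm_high_gray_level_zone_emphasis
glszm_large_area_emphasis
glszm_large_area_high_gray_level_emphasis
glszm_large_area_low_gray_level_emphasis
glszm_low_gray_level_zone_emphasis
glszm_size_zone_non_uniformity
glszm_size_zone_non_uniformity_normalized
glszm_small_area_emphasis
glszm_small_area_high_gray_level_emphasis
glszm_small_area_low_gray_level_emphasis
glszm_zone_entropy
glszm_zone_percentage
glszm_zone_variance
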