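roi_volume_mm3
adc_mean
adc_p25
adc_p50
adc_p75
adc_skewness
adc_kurtosis
adc_intensity_kurtosis
adc_intensity_variance
adc_intensity_hist_mean
adc_glcm_joint_maximum
adc_glcm_joint_average
adc_glcm_joint_variance
adc_glcm_joint_entropy
adc_glcm_difference_average
adc_glcm_difference_variance
adc_glcm_difference_entropy
adc_glcm_sum_average
adc_glcm_sum_variance
adc_glcm_sum_entropy
adc_glcm_angular_second_moment
adc_glcm_contrast
adc_glcm_dissimilarity
adc_glcm_inverse_difference
adc_glcm_inverse_difference_normalized
adc_glcm_inverse_difference_moment
adc_glcm_inverse_difference_moment_normalized
adc_glcm_inverse_variance
adc_glcm_correlation
adc_glcm_autocorrelation
adc_glcm_cluster_tendency
adc_glcm_cluster_shade
adc_glcm_cluster_prominence
adc_glcm_information_correlation_1
adc_glcm_information_correlation_2
t2w_glcm_joint_maximum
t2w_glcm_joint_average
t2w_glcm_joint_variance
t2w_glcm_joint_entropy
t2w_glcm_difference_average
t2w_glcm_difference_variance
t2w_glcm_difference_entropy
t2w_glcm_sum_average
t2w_glcm_sum_variance
t2w_glcm_sum_entropy
t2w_glcm_angular_second_moment
t2w_glcm_contrast
t2w_glcm_dissimilarity
t2w_glcm_inverse_difference
t2w_glcm_inverse_difference_normalized
t2w_glcm_inverse_difference_moment
t2w_glcm_inverse_difference_moment_normalized
t2w_glcm_inverse_variance
t2w_glcm_correlation
t2w_glcm_autocorrelation
t2w_glcm_cluster_tendency
t2w_glcm_cluster_shade
t2w_glcm_cluster_prominence
t2w_glcm_information_correlation_1
t2w_glcm_information_correlation_2
adc_glrlm_short_run_emphasis
adc_glrlm_long_run_emphasis
adc_glrlm_low_gray_level_run_emphasis
adc_glrlm_high_gray_level_run_emphasis
adc_glrlm_short_run_low_gray_level_emphasis
adc_glrlm_short_run_high_gray_level_emphasis
adc_glrlm_long_run_low_gray_level_emphasis
adc_glrlm_long_run_high_gray_level_emphasis
adc_glrlm_gray_level_non_uniformity
adc_glrlm_gray_level_non_uniformity_normalized
adc_glrlm_run_length_non_uniformity
adc_glrlm_run_length_non_uniformity_normalized
adc_glrlm_run_percentage
adc_glrlm_gray_level_variance
adc_glrlm_run_length_variance
adc_glrlm_run_entropy
t2w_glrlm_short_run_emphasis
t2w_glrlm_long_run_emphasis
t2w_glrlm_low_gray_level_run_emphasis
t2w_glrlm_high_gray_level_run_emphasis
t2w_glrlm_short_run_low_gray_level_emphasis
t2w_glrlm_short_run_high_gray_level_emphasis
t2w_glrlm_long_run_low_gray_level_emphasis
t2w_glrlm_long_run_high_gray_level_emphasis
t2w_glrlm_gray_level_non_uniformity
t2w_glrlm_gray_level_non_uniformity_normalized
t2w_glrlm_run_length_non_uniformity
t2w_glrlm_run_length_non_uniformity_normalized
t2w_glrlm_run_percentage
t2w_glrlm_gray_level_variance
t2w_glrlm_run_length_variance
t2w_glrlm_run_entropy
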