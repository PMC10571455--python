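name,value
glcm_d1_autocorrelation,154.93207099112612
glcm_d1_contrast,3.805274340707412
glcm_d1_correlation,0.9441208473515267
glcm_d1_cluster_prominence,53236.23633034605
glcm_d1_cluster_shade,1497.2631121919742
glcm_d1_dissimilarity,1.2902137232845896
glcm_d1_energy,0.030666764470339218
glcm_d1_entropy,5.95828199429511
glcm_d1_homogeneity,0.5858452199940763
glcm_d1_maximum_probability,0.07924009498812648
glcm_d1_sum_of_squares,34.04914140919237
glcm_d1_sum_average,22.161729783777027
glcm_d1_sum_variance,132.39129129606206
glcm_d1_sum_entropy,4.394451693233
glcm_d1_difference_variance,2.1406228889555283
glcm_d1_difference_entropy,2.1645336478248516
glcm_d2_autocorrelation,155.0311699948797
glcm_d2_contrast,8.657066052227343
glcm_d2_correlation,0.8743193877541933
glcm_d2_cluster_prominence,45712.45710457881
glcm_d2_cluster_shade,1347.0987025710315
glcm_d2_dissimilarity,1.9142345110087047
glcm_d2_energy,0.02607749486852975
glcm_d2_entropy,6.28528180264834
glcm_d2_homogeneity,0.5133580500755999
glcm_d2_maximum_probability,0.06726830517153098
glcm_d2_sum_of_squares,34.440737905126596
glcm_d2_sum_average,22.35343061955965
glcm_d2_sum_variance,129.10588556827906
glcm_d2_sum_entropy,4.384686271323098
glcm_d2_difference_variance,4.99277228909061
glcm_d2_difference_entropy,2.620822203496531
glcm_d3_autocorrelation,155.34721311475408
glcm_d3_contrast,13.282754098360655
glcm_d3_correlation,0.8093610235933437
glcm_d3_cluster_prominence,40649.27250637721
glcm_d3_cluster_shade,1208.5121773199055
glcm_d3_dissimilarity,2.3198688524590168
glcm_d3_energy,0.023627306638000535
glcm_d3_entropy,6.477986321358393
glcm_d3_homogeneity,0.4916037925644483
glcm_d3_maximum_probability,0.0641311475409836
glcm_d3_sum_of_squares,34.837456507390485
glcm_d3_sum_average,22.55226229508197
glcm_d3_sum_variance,126.0670719312013
glcm_d3_sum_entropy,4.500028100096172
glcm_d3_difference_variance,7.900962605751141
glcm_d3_difference_entropy,2.8363429867526366
image_entropy,3.5583264249597257
geom_centroid_offset,3.050027823160786
geom_major_axis_length,46.47756478928513
geom_minor_axis_length,37.438805833286075
geom_eccentricity,0.5925627998431843
geom_orientation,-1.3570373537718374
geom_convex_area,1521.0
geom_filled_area,1252.0
geom_euler_number,1.0
geom_equiv_diameter,39.926130666625134
geom_solidity,0.8231426692965155
geom_extent,0.5961904761904762
geom_perimeter,167.98275605729688
geom_perimeter_old,161.9391562052287
hu_1,-0.7500513421721245
hu_2,-2.8435376285716734
hu_3,-3.379780330299756
hu_4,-6.062451014300284
hu_5,12.041238835660003
hu_6,7.925226517103789
hu_7,10.784230542324098
intensity_mean,0.6030111150982992
intensity_variance,0.006550399852332536
intensity_skewness,2.4986022325705126
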