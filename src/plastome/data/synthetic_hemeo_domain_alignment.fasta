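>toyHO01 synthetic toy heme-oxygenase domain
VKTYFWQGTHRSTKVQSFSRRSEYHENQHTQHASVTHEDFNFEYVNNYYRHHRNKSTNHG
GAYVKQGVTQHEAFFGVQFRAQDKLQFVTHHRAAAWGFVHNNAAHTGLNHYFLSRRCHTK
>toyHO02 synthetic toy heme-oxygenase domain
VKRYFWQGRHRSTKHQSFSRRSCYHENLHTGHASQEHEDFNFEYVFNYYVHHRNKKTNHG
GAYTKQGVTYHEAMFGEQHPAQDKLQHVTHHRAAASGFVKNNAAHTGLNNYFLSRRAHTK
>toyHO03 synthetic toy heme-oxygenase domain
VKTYFWQGRHRSTKHQSFSRRSEYHENSHTGHTSCTHEDFNFEYVFNYYRHYRAKKTNHG
GAYEKQVVTQHEAFFGEQPHAQWKLQFVVHHRAAASGFVKNNAAHTGLNNYFLSRRKHTK
>toyHO04 synthetic toy heme-oxygenase domain
VKTYFWQGRARSTKHSSFSRRSEYHENQHTGHASATHEDFNTEYVFNYYRHHRNKKTNHG
GAYVKQEVTQHEAFFGTQFRIQDKLQFVTHHRAAASGFVKNNAAHTGWNNYFLSRRAHTK
>toyHO05 synthetic toy heme-oxygenase domain
VKTYFWQGRHRSTKHQSFSRRSEYHENQHTGHASVTHEDYNFEYVFNYFRHHRNKKTNHG
GAYRKQGVTQHEAFWGEQFRAQDKLQFVAHHRAAASIFVKNNAKHTGLNNYFLSRYAHTK
>toyHO06 synthetic toy heme-oxygenase domain
VKTYFWQGRHRSTKHHSFSRRSMYHENRHTGHASVTHEDFNFNYVFNYYRHHRTKKANHG
GAYTKQGVTVHEAFFGEQFRAQDKLQFVTHHRAAASGFVTNNAARTGVHNYFLSQEAHTK
>toyHO07 synthetic toy heme-oxygenase domain
VKRYFWQGRHRSTKHHSFSRRSEYHENHHTGWASVTTEFCNFNYRFNYYRHHRNYKTVHG
GAYVAQGVTQHEAFFGWQFRAQDKLNFVTHHRAAASGFVKNNAAHTGLNNYFLSRRAHTK
>toyHO08 synthetic toy heme-oxygenase domain
LKTYFWQGRHRSTKHQSFSRRSEYHENQHTWHASVTHEDFNFEYVFNYYRYHRNHKTNHG
GAYVKAGVAQHGAFFGEQFRAQDKLQFVVHHRAAPWYFVKNNAAHTGLNNYFLSRRAHTK
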